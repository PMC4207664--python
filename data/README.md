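# External datasets

The checks in `tests/test_acceptance.py::TestPublishedHIFTable` validate the
HIF mixed models against the published greenhouse phenotype and qPCR
supplementary datasets, which are not redistributable within this
repository. To run them, download the two supplementary data files of the
source study (the HIF phenotype table and the FT-expression ΔCt table) and
save them here as:

- `data/dataset_s1.txt` — columns: Block, Flowering_time,
  Leaf_number_at_flowering, Height_at_flowering, nFT_genotype, HIF, Family
- `data/dataset_s2.txt` — columns: Plant_ID, HIF, Family, nFT_genotype,
  Visible_bud, delta_Ct

Without these files those specific checks fail with a pointer to this note;
everything else runs on simulated data.
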