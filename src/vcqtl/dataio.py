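"""Tabular data model and readers/writers for the (co)variance-QTL pipeline.

The pipeline operates on four kinds of tables:

* a genetic map (marker, linkage group, position in cM),
* a recombinant-inbred-line (RIL) genotype matrix coded as the two parental
  homozygote classes (``CO``/``MT``) plus missing,
* family-mean phenotypes, one column per trait-by-environment combination,
* heterogeneous-inbred-family (HIF) phenotype and qPCR expression tables.

Everything is plain delimited text (tab or comma, auto-detected); readers
validate invariants eagerly and never drop rows silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("vcqtl")

# canonical internal genotype codes
CO, MT, MISSING = 0, 1, -1
CODE_LABELS = {CO: "CO", MT: "MT", MISSING: "NA"}

#: default cell-code vocabulary for genotype files; configurable per read.
DEFAULT_GENOTYPE_CODES = {"CO": CO, "MT": MT, "HET": MISSING, "NA": MISSING}


class ParseError(ValueError):
    """Raised when an input table violates the format contract."""


def _read_delimited(path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table with a header row."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True, comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{what}: missing required column(s) {missing}; "
            f"expected header with {list(required)}, got {list(df.columns)}"
        )


@dataclass
class GeneticMap:
    """Ordered marker map: marker id, linkage group, position (cM)."""

    table: pd.DataFrame  # columns: marker, linkage_group, cM

    def __post_init__(self):
        t = self.table
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ParseError(f"duplicate marker id {dup!r} in genetic map")
        for lg, sub in t.groupby("linkage_group", sort=False):
            pos = sub["cM"].to_numpy(float)
            if (pos < 0).any():
                raise ParseError(f"negative cM position on linkage group {lg}")
            if (np.diff(pos) < 0).any():
                raise ParseError(
                    f"positions not non-decreasing on linkage group {lg}")

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, lg) -> np.ndarray:
        return self.table.loc[self.table["linkage_group"] == lg,
                              "cM"].to_numpy(float)

    @property
    def linkage_groups(self) -> list:
        return list(dict.fromkeys(self.table["linkage_group"]))


def read_map(path) -> GeneticMap:
    """Read a genetic map with columns ``marker``, ``linkage_group``, ``cM``."""
    df = _read_delimited(path)
    _require_columns(df, ["marker", "linkage_group", "cM"], "genetic map")
    out = pd.DataFrame({"marker": df["marker"].str.strip()})
    try:
        out["linkage_group"] = df["linkage_group"].astype(int)
    except ValueError as exc:
        raise ParseError(f"non-integer linkage group in map: {exc}") from None
    try:
        out["cM"] = df["cM"].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric cM position in map: {exc}") from None
    return GeneticMap(out.reset_index(drop=True))


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Families x markers matrix of homozygote-class calls.

    ``codes`` holds int8 values: 0 = CO homozygote, 1 = MT homozygote,
    -1 = missing (heterozygous calls are coerced to missing on read, as the
    analyses only contrast the two homozygote classes).
    """

    families: list[str]
    map: GeneticMap
    codes: np.ndarray  # (n_families, n_markers) int8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.families), self.map.n_markers):
            raise ValueError(
                f"genotype codes shape {self.codes.shape} does not match "
                f"{len(self.families)} families x {self.map.n_markers} markers")
        bad = ~np.isin(self.codes, (CO, MT, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0 (CO), 1 (MT), -1}")

    @property
    def markers(self) -> list[str]:
        return self.map.markers

    @property
    def n_families(self) -> int:
        return len(self.families)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.markers.index(marker_id)
        except ValueError:
            raise KeyError(f"marker {marker_id!r} not in genotype matrix") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.marker_index(marker_id)]

    def allele_frequency(self, which: int = MT) -> np.ndarray:
        """Per-marker frequency of one homozygote class among non-missing calls."""
        obs = self.codes != MISSING
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (self.codes == which).sum(axis=0) / n, np.nan)

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        keep = [self.marker_index(m) for m in marker_ids]
        sub_map = GeneticMap(self.map.table.iloc[keep].reset_index(drop=True))
        return GenotypeMatrix(list(self.families), sub_map, self.codes[:, keep])

    def to_frame(self) -> pd.DataFrame:
        labels = np.array([CODE_LABELS[CO], CODE_LABELS[MT]] + [CODE_LABELS[MISSING]])
        # codes -1 -> index 2
        lab = labels[self.codes]
        return pd.DataFrame(lab, index=pd.Index(self.families, name="family"),
                            columns=self.markers)


def read_genotypes(path, gmap: GeneticMap,
                   codes: dict | None = None) -> GenotypeMatrix:
    """Read a families x markers genotype table against a genetic map.

    Heterozygous and missing cell codes both map to MISSING. Every marker
    column in the file must exist in the map; the returned matrix carries
    exactly the map's marker set in map order.
    """
    code_map = dict(DEFAULT_GENOTYPE_CODES if codes is None else codes)
    df = _read_delimited(path)
    _require_columns(df, ["family"], "genotype matrix")
    file_markers = [c for c in df.columns if c != "family"]
    unknown = [m for m in file_markers if m not in set(gmap.markers)]
    if unknown:
        raise ParseError(f"genotype file marker(s) {unknown[:5]} absent from map")
    absent = [m for m in gmap.markers if m not in set(file_markers)]
    if absent:
        raise ParseError(f"map marker(s) {absent[:5]} absent from genotype file")
    families = [str(f) for f in df["family"]]
    n_het = 0
    arr = np.empty((len(families), gmap.n_markers), dtype=np.int8)
    for j, m in enumerate(gmap.markers):
        col = df[m].fillna("NA").str.strip()
        vals = np.empty(len(col), dtype=np.int8)
        for i, cell in enumerate(col):
            if cell not in code_map:
                raise ParseError(
                    f"unknown genotype code {cell!r} at family "
                    f"{families[i]!r}, marker {m!r}")
            vals[i] = code_map[cell]
            if cell == "HET":
                n_het += 1
        arr[:, j] = vals
    if n_het:
        logger.info("read_genotypes: coerced %d heterozygous calls to missing",
                    n_het)
    return GenotypeMatrix(families, gmap, arr)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    geno.to_frame().to_csv(path, sep="\t")


@dataclass
class PhenotypeTable:
    """Family-mean trait values; one column per trait x environment combination."""

    table: pd.DataFrame  # index: family_id, columns: trait ids, float values
    standardized: bool = False
    parental_lines: list[str] = field(default_factory=list)

    @property
    def traits(self) -> list[str]:
        return list(self.table.columns)

    @property
    def families(self) -> list[str]:
        return list(self.table.index)

    def values_for(self, trait: str, families=None) -> np.ndarray:
        col = self.table[trait]
        if families is not None:
            col = col.reindex(families)
        return col.to_numpy(float)

    def drop_parental(self) -> "PhenotypeTable":
        """RIL-only view: scans contrast genotype classes among RILs."""
        if not self.parental_lines:
            return self
        keep = [f for f in self.families if f not in set(self.parental_lines)]
        return PhenotypeTable(self.table.loc[keep], self.standardized, [])


def read_phenotypes(path, parental_lines=None) -> PhenotypeTable:
    """Read family-mean phenotypes (column ``family`` + one column per trait)."""
    df = _read_delimited(path)
    _require_columns(df, ["family"], "phenotype table")
    out = df.set_index("family")
    out.index = out.index.map(str)
    try:
        out = out.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric phenotype value: {exc}") from None
    return PhenotypeTable(out, parental_lines=list(parental_lines or []))


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.table.to_csv(path, sep="\t", index_label="family")


HIF_COLUMNS = ["Block", "Flowering_time", "Leaf_number_at_flowering",
               "Height_at_flowering", "nFT_genotype", "HIF", "Family"]

EXPRESSION_COLUMNS = ["Plant_ID", "HIF", "Family", "nFT_genotype",
                      "Visible_bud", "delta_Ct"]


def _check_family_nesting(df: pd.DataFrame, what: str) -> None:
    """Each Family must belong to a single (HIF, nFT_genotype) pair."""
    counts = df.groupby("Family")[["HIF", "nFT_genotype"]].nunique()
    bad = counts[(counts > 1).any(axis=1)]
    if len(bad):
        raise ParseError(
            f"{what}: Family level(s) {list(bad.index)[:5]} appear under more "
            "than one (HIF, nFT_genotype) combination; families must nest")


def read_hif_table(path) -> pd.DataFrame:
    """Read a HIF greenhouse phenotype table (Dataset S1 layout)."""
    df = _read_delimited(path)
    _require_columns(df, HIF_COLUMNS, "HIF table")
    out = df[HIF_COLUMNS].copy()
    for col in ("Flowering_time", "Leaf_number_at_flowering",
                "Height_at_flowering"):
        out[col] = out[col].astype(float)
    for col in ("Block", "nFT_genotype", "HIF", "Family"):
        out[col] = out[col].astype(str).str.strip()
    genos = set(out["nFT_genotype"].unique())
    if not genos <= {"CO", "MT"}:
        raise ParseError(f"HIF table: nFT_genotype must be CO/MT, got {genos}")
    _check_family_nesting(out, "HIF table")
    return out


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}


def read_expression_table(path) -> pd.DataFrame:
    """Read a qPCR expression table (Dataset S2 layout).

    delta_Ct is reference-gene Ct minus target Ct; in the flowering-time
    regime it is expected to be negative (the target amplifies later than the
    reference). Positive values are loaded but draw a warning.
    """
    df = _read_delimited(path)
    _require_columns(df, EXPRESSION_COLUMNS, "expression table")
    out = df[EXPRESSION_COLUMNS].copy()
    out["delta_Ct"] = out["delta_Ct"].astype(float)
    if not np.isfinite(out["delta_Ct"]).all():
        raise ParseError("expression table: non-finite delta_Ct value")
    for col in ("Plant_ID", "HIF", "Family", "nFT_genotype"):
        out[col] = out[col].astype(str).str.strip()
    bud = out["Visible_bud"].astype(str).str.strip().str.lower()
    unknown = set(bud) - _TRUE - _FALSE
    if unknown:
        raise ParseError(f"expression table: Visible_bud values {unknown} "
                         "not interpretable as boolean")
    out["Visible_bud"] = bud.isin(_TRUE)
    _check_family_nesting(out, "expression table")
    n_pos = int((out["delta_Ct"] >= 0).sum())
    if n_pos:
        warnings.warn(
            f"expression table: {n_pos} delta_Ct value(s) are >= 0; "
            "expected negative (target Ct above reference Ct)",
            UserWarning, stacklevel=2)
    return out


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
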