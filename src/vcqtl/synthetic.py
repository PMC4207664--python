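"""Synthetic RIL / HIF data with the statistical structure the scans assume.

The generator embodies a threshold-liability picture of flowering time: a
focal locus (the ``nFT``-like major QTL) carries a genotype-specific
expression threshold, many small-effect background loci plus the environment
supply a quantitative input signal ``x``, and the probability that an
individual flowers in the first growing season follows the sigmoid

    y = 1 / (1 + exp(a * (-x + b_G)))

where ``b_G`` is the threshold of the focal genotype (the early-flowering
class has the lower threshold, b_MT < b_CO).  Individuals that do not flower
in season one flower in season two, after the 180-day season boundary.  This
single mechanism produces, depending on the environmental signal offset,
either no variance difference between focal-genotype classes (signal
saturating for both), excess among-family variance in the high-threshold
class (signal straddling only its threshold), or excess variance in the
low-threshold class (signal straddling only the low threshold) -- i.e. a
canalization effect whose direction reverses across environments.

Six default environments are calibrated so the simulated grand-mean
flowering times bracket realistic values for a montane mustard: two
flowering-promoting chambers, two slightly inhibiting, two strongly
inhibiting (in which most families of the high-threshold class defer
flowering to season two).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CO, MT, MISSING, GeneticMap, GenotypeMatrix, PhenotypeTable

#: season boundary (days): season-1 flowering happens strictly before this,
#: season-2 strictly after.
SEASON_BOUNDARY = 180.0

#: default environment names by category
PROMOTING_ENVS = ("16h18C4w", "16h18C6w")
SLIGHTLY_INHIBITING_ENVS = ("12h18C4w", "12h18C6w")
STRONGLY_INHIBITING_ENVS = ("16h25C4w", "16h25C6w")
DEFAULT_ENVIRONMENTS = (
    PROMOTING_ENVS + SLIGHTLY_INHIBITING_ENVS + STRONGLY_INHIBITING_ENVS
)

DEFAULT_ENV_OFFSETS = {
    # promoting: signal saturates above both thresholds for every background
    "16h18C4w": 2.6,
    "16h18C6w": 3.0,
    # slightly inhibiting: signal straddles the high (CO) threshold only
    "12h18C4w": -0.4,
    "12h18C6w": -0.15,
    # strongly inhibiting: signal straddles the low (MT) threshold only,
    # nearly all high-threshold families defer to season two
    "16h25C4w": -3.0,
    "16h25C6w": -2.7,
}


def sigmoid_response(x, a, b):
    """Probability of expression given input signal x, steepness a, threshold b."""
    from scipy.special import expit

    return expit(a * (np.asarray(x, float) - b))


@dataclass
class ThresholdModel:
    """Parameters of the threshold/sigmoid flowering simulator.

    Signal units are arbitrary; days are days after the end of the first
    vernalization (the second vernalization period is never added back).
    """

    a: float = 15.0                # sigmoid steepness (1/signal unit)
    b_CO: float = 2.2              # high threshold (signal units)
    b_MT: float = 0.0              # low threshold (signal units)
    #: marker_id -> additive signal contribution of the MT allele
    background_effects: dict = field(default_factory=dict)
    #: environment -> additive signal offset
    env_offsets: dict = field(default_factory=lambda: dict(DEFAULT_ENV_OFFSETS))
    noise_sd: float = 0.3          # individual signal noise SD
    season1_base: float = 150.0    # days; season-1 time = base - slope_c * x
    season2_base: float = 260.0    # days; well past the 180-day boundary
    slope_c: float = 3.0           # days earlier per signal unit
    leaf_coupling: float = 0.18    # leaves per day of flowering time
    day_noise_sd: float = 6.0      # within-season flowering-day noise (days)
    season2_sd: float = 12.0       # season-2 flowering-day spread (days)
    leaf_noise_sd: float = 1.5     # leaf-count noise

    def __post_init__(self):
        if not self.b_MT < self.b_CO:
            raise ValueError("threshold model requires b_MT < b_CO "
                             "(the early class has the lower threshold)")
        if self.a <= 0:
            raise ValueError("sigmoid steepness a must be > 0")
        if not self.season2_base > SEASON_BOUNDARY:
            raise ValueError("season2_base must exceed the 180-day boundary")

    def threshold_for(self, code: int) -> float:
        if code == CO:
            return self.b_CO
        if code == MT:
            return self.b_MT
        # residual heterozygote recorded as missing: intermediate threshold
        return 0.5 * (self.b_CO + self.b_MT)


@dataclass
class RILDesign:
    """A biparental recombinant-inbred design: map + family count + selfing depth."""

    map: GeneticMap
    n_families: int = 178
    selfing_generations: int = 5   # F1 -> F6

    def __post_init__(self):
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        if self.map.n_markers == 0:
            raise ValueError("empty genetic map")


def default_map(n_markers: int = 164, n_linkage_groups: int = 7,
                spacing_cM: float = 5.5) -> GeneticMap:
    """Evenly spaced marker map: n_markers split across linkage groups."""
    base = n_markers // n_linkage_groups
    extra = n_markers % n_linkage_groups
    rows = []
    k = 0
    for lg in range(1, n_linkage_groups + 1):
        n = base + (1 if lg <= extra else 0)
        for i in range(n):
            k += 1
            rows.append((f"M{k:03d}", lg, i * spacing_cM))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "linkage_group", "cM"]))


def default_focal_marker(gmap: GeneticMap) -> str:
    """Middle marker of the first linkage group (the nFT-like focal locus)."""
    lg = gmap.linkage_groups[0]
    sub = gmap.table[gmap.table["linkage_group"] == lg]
    return str(sub["marker"].iloc[len(sub) // 2])


def default_background_effects(gmap: GeneticMap, focal_marker: str,
                               n_loci: int = 12,
                               beta: float = 0.5) -> dict:
    """Equal-effect background loci spread over non-focal linkage groups."""
    focal_lg = int(gmap.table.loc[gmap.table["marker"] == focal_marker,
                                  "linkage_group"].iloc[0])
    other = [lg for lg in gmap.linkage_groups if lg != focal_lg]
    per_lg = max(1, int(round(n_loci / len(other)))) if other else n_loci
    chosen: list[str] = []
    for lg in other:
        sub = gmap.table[gmap.table["linkage_group"] == lg]["marker"].tolist()
        # spread within the group, avoiding the ends
        idx = np.linspace(0, len(sub) - 1, per_lg + 2)[1:-1]
        chosen.extend(sub[int(round(i))] for i in idx)
        if len(chosen) >= n_loci:
            break
    chosen = chosen[:n_loci]
    return {m: beta for m in chosen}


def default_model(gmap: GeneticMap, focal_marker: str | None = None,
                  **overrides) -> ThresholdModel:
    """ThresholdModel with default background loci wired to a map."""
    if focal_marker is None:
        focal_marker = default_focal_marker(gmap)
    bg = overrides.pop("background_effects", None)
    if bg is None:
        bg = default_background_effects(gmap, focal_marker)
    return ThresholdModel(background_effects=bg, **overrides)


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction from map distance under the Haldane map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def _interval_recomb(gmap: GeneticMap) -> np.ndarray:
    """Per-marker switch probability for a gamete's Markov walk along the map.

    Entry 0 is 0.5 (free choice of starting strand); within a linkage group
    the entry is the Haldane recombination fraction to the previous marker;
    at a linkage-group boundary it is 0.5 (independent assortment).
    """
    lg = gmap.table["linkage_group"].to_numpy()
    pos = gmap.table["cM"].to_numpy(float)
    p = np.empty(len(lg))
    p[0] = 0.5
    same = lg[1:] == lg[:-1]
    p[1:] = np.where(same, _haldane_r(np.abs(np.diff(pos))), 0.5)
    return p


def _gametes(h0: np.ndarray, h1: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete per family from a diploid (h0, h1) haplotype pair."""
    n_fam, n_mark = h0.shape
    switches = rng.random((n_fam, n_mark)) < switch_p[None, :]
    strand = np.cumsum(switches, axis=1) % 2
    return np.where(strand == 0, h0, h1)


def simulate_ril_genotypes(design: RILDesign, seed: int) -> GenotypeMatrix:
    """Simulate RIL genotypes by repeated selfing from a fully heterozygous F1.

    Crossovers are drawn independently per meiosis under the Haldane map
    function (no interference). After the configured number of selfing
    generations a marker still heterozygous is recorded as missing, matching
    how heterozygous calls are treated on data read-in. The expected residual
    heterozygosity per marker is 2^-(selfing generations).
    """
    rng = np.random.default_rng(seed)
    gmap = design.map
    switch_p = _interval_recomb(gmap)
    n_fam, n_mark = design.n_families, gmap.n_markers
    h0 = np.zeros((n_fam, n_mark), dtype=np.int8)   # CO haplotype
    h1 = np.ones((n_fam, n_mark), dtype=np.int8)    # MT haplotype
    for _ in range(design.selfing_generations):
        g0 = _gametes(h0, h1, switch_p, rng)
        g1 = _gametes(h0, h1, switch_p, rng)
        h0, h1 = g0, g1
    codes = np.where(h0 == h1,
                     np.where(h0 == 0, CO, MT),
                     MISSING).astype(np.int8)
    families = [f"RIL{i + 1:03d}" for i in range(n_fam)]
    return GenotypeMatrix(families, gmap, codes)


def _allele_dose(codes: np.ndarray) -> np.ndarray:
    """MT-allele dose per call: CO -> 0, MT -> 1, missing (residual het) -> 0.5."""
    dose = codes.astype(float)
    dose[codes == MISSING] = 0.5
    return dose


def _draw_times(x: np.ndarray, b: np.ndarray, model: ThresholdModel,
                rng: np.random.Generator):
    """Flowering day and season for individuals with signal x and threshold b."""
    y = sigmoid_response(x, model.a, b)
    season1 = rng.random(x.shape) < y
    t1 = model.season1_base - model.slope_c * x \
        + rng.normal(0.0, model.day_noise_sd, x.shape)
    t1 = np.minimum(t1, SEASON_BOUNDARY - 1.0)
    t2 = model.season2_base + rng.normal(0.0, model.season2_sd, x.shape)
    t2 = np.maximum(t2, SEASON_BOUNDARY + 1.0)
    t = np.where(season1, t1, t2)
    leaves = model.leaf_coupling * t + rng.normal(0.0, model.leaf_noise_sd,
                                                  x.shape)
    return t, leaves, season1


def simulate_threshold_phenotypes(
    genotypes: GenotypeMatrix,
    model: ThresholdModel,
    focal_marker: str,
    environments=None,
    n_reps_per_family: int = 5,
    seed: int = 0,
    return_individuals: bool = False,
):
    """Family-mean flowering time and leaf number across environments.

    Per individual the input signal is
    ``x = sum(beta_m * MT-allele dose at background locus m) + env offset
    + Normal(0, noise_sd)``; the focal-marker genotype sets the sigmoid
    threshold. Returns a :class:`PhenotypeTable` of family means with trait
    ids ``flowering-time@<env>`` and ``leaf-number@<env>`` (and, if
    ``return_individuals``, a long DataFrame of individual draws as well).
    """
    if environments is None:
        environments = [e for e in DEFAULT_ENVIRONMENTS
                        if e in model.env_offsets]
    missing_envs = [e for e in environments if e not in model.env_offsets]
    if missing_envs:
        raise KeyError(f"no env offset for environment(s) {missing_envs}")
    if n_reps_per_family <= 0:
        raise ValueError("n_reps_per_family must be positive")
    focal = genotypes.column(focal_marker)  # KeyError if absent
    rng = np.random.default_rng(seed)
    n_fam = genotypes.n_families

    x_bg = np.zeros(n_fam)
    for m, beta in model.background_effects.items():
        x_bg += beta * _allele_dose(genotypes.column(m))
    b_fam = np.array([model.threshold_for(c) for c in focal])

    cols = {}
    individuals = []
    shape = (n_fam, n_reps_per_family)
    for env in environments:
        x = (x_bg[:, None] + model.env_offsets[env]
             + rng.normal(0.0, model.noise_sd, shape))
        t, leaves, season1 = _draw_times(x, b_fam[:, None], model, rng)
        cols[f"flowering-time@{env}"] = t.mean(axis=1)
        cols[f"leaf-number@{env}"] = leaves.mean(axis=1)
        if return_individuals:
            individuals.append(pd.DataFrame({
                "family": np.repeat(genotypes.families, n_reps_per_family),
                "environment": env,
                "flowering_time": t.ravel(),
                "leaf_number": leaves.ravel(),
                "season1": season1.ravel(),
            }))
    table = pd.DataFrame(cols, index=pd.Index(genotypes.families,
                                              name="family"))
    phen = PhenotypeTable(table)
    if return_individuals:
        return phen, pd.concat(individuals, ignore_index=True)
    return phen


#: default HIF background signal levels relative to thresholds (b_MT=0, b_CO=2.2):
#: between the thresholds, above both, between, below both.
DEFAULT_HIF_BACKGROUNDS = (1.1, 3.3, 0.7, -0.9)


def simulate_hif(
    model: ThresholdModel,
    n_hifs: int = 4,
    families_per_hif: int = 22,
    sibs_per_family: int = 9,
    n_blocks: int = 9,
    seed: int = 0,
    hif_backgrounds=None,
    family_sd: float = 0.2,
    block_sd_days: float = 4.0,
    height_base: float = 30.0,
    height_mt_effect: float = -2.0,
    height_noise_sd: float = 3.0,
) -> pd.DataFrame:
    """Simulate a balanced heterogeneous-inbred-family greenhouse experiment.

    Each HIF shares one fixed background signal level; families within a HIF
    get small signal deviations (held fixed across their siblings) and are
    split evenly between the two focal-locus homozygotes. A true genotype-by-
    background interaction on flowering exists exactly when the background
    levels straddle one of the two thresholds.
    """
    if n_hifs < 2:
        raise ValueError("need at least 2 HIFs for an interaction test")
    if sibs_per_family <= 0 or families_per_hif <= 0:
        raise ValueError("sibs_per_family and families_per_hif must be positive")
    if hif_backgrounds is None:
        hif_backgrounds = DEFAULT_HIF_BACKGROUNDS[:n_hifs]
        if len(hif_backgrounds) < n_hifs:
            raise ValueError("supply hif_backgrounds for n_hifs > 4")
    if len(hif_backgrounds) != n_hifs:
        raise ValueError("hif_backgrounds length must equal n_hifs")
    rng = np.random.default_rng(seed)
    block_effects = rng.normal(0.0, block_sd_days, n_blocks)
    rows = []
    for h in range(n_hifs):
        hif_name = f"HIF{h + 1}"
        for f in range(families_per_hif):
            geno = CO if f % 2 == 0 else MT
            geno_label = "CO" if geno == CO else "MT"
            fam_name = f"{hif_name}_F{f + 1:02d}"
            fam_signal = hif_backgrounds[h] + rng.normal(0.0, family_sd)
            fam_day_dev = rng.normal(0.0, 2.0)
            fam_height_dev = rng.normal(0.0, 2.0)
            b = model.threshold_for(geno)
            for s in range(sibs_per_family):
                block = s % n_blocks
                x = fam_signal + rng.normal(0.0, model.noise_sd)
                t, leaves, _ = _draw_times(np.array([x]), np.array([b]),
                                           model, rng)
                t = float(t[0]) + fam_day_dev + block_effects[block]
                lv = float(leaves[0])
                height = (height_base
                          + (height_mt_effect if geno == MT else 0.0)
                          + 0.5 * x + fam_height_dev
                          + rng.normal(0.0, height_noise_sd))
                rows.append((f"B{block + 1}", t, lv, height, geno_label,
                             hif_name, fam_name))
    return pd.DataFrame(rows, columns=[
        "Block", "Flowering_time", "Leaf_number_at_flowering",
        "Height_at_flowering", "nFT_genotype", "HIF", "Family"])


def simulate_expression(
    model: ThresholdModel,
    n_hifs: int = 2,
    families_per_genotype: int = 5,
    plants_per_family: int = 2,
    seed: int = 0,
    hif_backgrounds=(0.9, 3.1),
    dct_base: float = -9.0,
    dct_gain: float = 4.0,
    family_sd: float = 0.3,
    noise_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a qPCR ΔCt table under the same sigmoid expression rules.

    Expression of the focal gene tracks the sigmoid response y of the plant's
    genotype at its background signal level: ΔCt = dct_base + dct_gain * y
    plus family and plant noise (kept in the negative-ΔCt regime by default).
    Visible-bud status is drawn with probability y, so bud presence and ΔCt
    are positively associated.
    """
    if n_hifs < 2:
        raise ValueError("need at least 2 HIFs for an interaction test")
    if len(hif_backgrounds) != n_hifs:
        raise ValueError("hif_backgrounds length must equal n_hifs")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for h in range(n_hifs):
        hif_name = f"HIF{h + 1}"
        for geno, geno_label in ((CO, "CO"), (MT, "MT")):
            b = model.threshold_for(geno)
            for f in range(families_per_genotype):
                fam_name = f"{hif_name}_{geno_label}_F{f + 1}"
                fam_dev = rng.normal(0.0, family_sd)
                for _ in range(plants_per_family):
                    pid += 1
                    x = hif_backgrounds[h] + rng.normal(0.0, model.noise_sd)
                    y = float(sigmoid_response(x, model.a, b))
                    dct = dct_base + dct_gain * y + fam_dev \
                        + rng.normal(0.0, noise_sd)
                    bud = bool(rng.random() < y)
                    rows.append((f"P{pid:03d}", hif_name, fam_name,
                                 geno_label, bud, dct))
    return pd.DataFrame(rows, columns=[
        "Plant_ID", "HIF", "Family", "nFT_genotype", "Visible_bud",
        "delta_Ct"])
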