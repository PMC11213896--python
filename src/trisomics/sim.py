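"""Synthetic multiomics cohort generator with planted latent structure.

The generator emulates the statistical structure the analysis pipeline is
designed to detect: a chromosome-21 dosage effect with per-gene and
per-individual variation, two anti-correlated co-expressed gene clusters,
three latent molecular subtypes with graded cluster expression, an
inflammatory (MS3) analyte signature, graded amino-acid depletion, an
amino-acid transporter panel with planted up/down members, subtype shifts in
immune-cell composition and CBC parameters, covariate effects, and
longitudinal revisits with analyte-specific stability.  Every planted effect
is recorded in per-layer ``feature_truth`` tables so downstream stages can be
tested against ground truth.

All signal models live on the log2 scale; emitted matrices are positive
linear-scale values (2**log2).  One master seed spawns a named substream per
layer, so adding a layer does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix

__all__ = ["SimConfig", "MultiOmicsCohort", "substream", "simulate_samples",
           "simulate_expression", "simulate_panels", "simulate_metabolome",
           "simulate_cells_and_cbc", "simulate_revisit", "simulate_cohort"]

SUBTYPES = ("MS1", "MS2", "MS3")

#: analytes defining the inflammatory composite score
SCORE_ANALYTES = ("IL-6", "CRP", "SAA", "IL-22", "MIP-3alpha", "IL-15", "IL-1RN")

#: acute-phase / inflammation-related proteins planted in the broad proteome
ACUTE_PHASE_PROTEINS = ("CRP", "IL-6", "SAA1", "SAA2", "IL-1RN",
                        "LCN2", "PROK2", "BPI", "MPO", "PRTN3")

AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "L-citrulline",
    "gamma-L-glutamyl-D-alanine", "glutamine", "glutamate", "glycine",
    "histidine", "isoleucine", "leucine", "lysine", "methionine",
    "phenylalanine", "proline", "serine", "threonine", "tryptophan",
    "tyrosine", "valine",
)

#: the nine analytes carrying an extra MS3-vs-MS1 depletion effect
DEPLETED_ANALYTES = ("asparagine", "serine", "proline", "alanine", "threonine",
                     "histidine", "L-citrulline", "gamma-L-glutamyl-D-alanine",
                     "glycine")

CELL_TYPES = ("neutrophils", "t_cells", "b_cells", "nk_cells", "monocytes", "other")

CBC_FEATURES = ("wbc", "rbc", "hemoglobin", "hematocrit", "mcv", "mch",
                "platelets", "abs_lymphocytes", "pct_lymphocytes",
                "abs_neutrophils", "pct_neutrophils")


@dataclass(frozen=True)
class CovariateEffects:
    """Log2-scale covariate contributions applied to every layer."""

    age_slope: float = 0.004          # per year
    sex_offset: float = 0.06          # M relative to F
    source_offset: float = 0.10       # site B relative to A


@dataclass(frozen=True)
class PanelConfig:
    """Targeted cytokine panel and broad proteome calibration (SD units)."""

    n_msd: int = 54
    msd_noise_sd: float = 1.0
    score_ms3_shift: float = 2.2      # z-shift of the 7 score analytes in MS3
    score_other_shift: float = 0.4    # ... in MS1/MS2
    shared_analytes: tuple = ("IL-10", "TSLP", "TNF-alpha")
    shared_shift: float = 1.0         # elevated in every subtype
    ms1_analytes: tuple = ("IL-8", "eotaxin", "FGF-basic")
    ms1_shift: float = 0.8
    n_soma: int = 100
    soma_noise_sd: float = 0.5
    soma_ms3_shift: float = 3.0       # acute-phase proteins in MS3
    soma_other_shift: float = 0.9     # ... in MS1/MS2


@dataclass(frozen=True)
class MetabConfig:
    """Metabolome layer: graded amino-acid depletion, planted MS3 analytes."""

    n_features: int = 40
    n_planted: int = 9
    t21_aa_shift: float = -0.4                      # all amino acids, any subtype
    planted_shifts: tuple = (0.0, -0.35, -1.2)      # extra per subtype (MS1..MS3)
    noise_sd: float = 0.4
    zero_rate: float = 0.01
    sample_scale_sd: float = 0.2


@dataclass(frozen=True)
class TransporterConfig:
    """Amino-acid transporter expression panel planted in the transcriptome."""

    n_up: int = 18
    n_down: int = 12
    n_neutral: int = 1
    up_shifts: tuple = (0.0, 0.4, 0.9)      # per subtype (MS1..MS3), log2
    down_shifts: tuple = (0.0, -0.4, -0.9)


@dataclass(frozen=True)
class CellConfig:
    """Immune-cell composition and CBC calibration (shifts in SD units)."""

    noise_sd: float = 0.35
    base_fractions: tuple = (0.55, 0.22, 0.07, 0.05, 0.08, 0.03)
    neutro_shifts: tuple = (0.8, 0.8, 4.0)      # per subtype
    lymph_shifts: tuple = (-0.45, -0.45, -1.5)  # t/b/nk cells per subtype
    cbc_noise_sd: float = 0.45
    cbc_lymph_shifts: tuple = (-0.4, -0.4, -2.2)
    cbc_neutro_shifts: tuple = (0.3, 0.3, 1.0)
    mcv_t21_shift: float = 1.2


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic cohort."""

    n_controls: int = 96
    subtype_sizes: tuple = (107, 95, 102)
    n_hsa21_coding: int = 126
    gene_cluster_sizes: tuple = (97, 29)
    n_background_genes: int = 2000
    dosage_log2fc: float = float(np.log2(1.5))
    dosage_gene_sd: float = 0.18        # per-gene variation of the dosage effect
    # per-subtype log2 modifiers for gene clusters 1 and 2 (MS1, MS2, MS3);
    # weighted means over the default subtype sizes are ~0 so the cohort-wide
    # dosage ratio stays at 2**dosage_log2fc
    cluster1_effects: tuple = (1.5, 0.0, -1.57)
    cluster2_effects: tuple = (-1.0, -0.26, 1.29)
    effect_jitter: float = 0.15         # per-gene multiplier ~ U(1-j, 1+j)
    # per-gene, per-subtype fingerprint offsets (log2 SD).  These give every
    # subtype its own multi-gene signature (a pure shared-axis gradient would
    # leave the middle subtype without any co-expression cohesion)
    subtype_profile_sd: float = 0.55
    latent_loading: float = 0.5
    latent_gene_range: tuple = (0.10, 0.24)
    noise_sd: float = 0.5
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    metab_config: MetabConfig = field(default_factory=MetabConfig)
    transporter_config: TransporterConfig = field(default_factory=TransporterConfig)
    cell_config: CellConfig = field(default_factory=CellConfig)
    stability_rho: tuple = (("default", 0.5), ("score", 0.85))
    n_revisit: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_controls, self.n_hsa21_coding, self.n_background_genes,
                  *self.subtype_sizes, *self.gene_cluster_sizes]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be > 0")
        if len(self.subtype_sizes) != 3:
            raise ValueError("exactly 3 subtypes are modelled")
        if sum(self.gene_cluster_sizes) > self.n_hsa21_coding:
            raise ValueError("gene cluster sizes exceed the number of coding genes")
        if not (0.0 <= self.latent_loading <= 1.0):
            raise ValueError("latent_loading must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        mc = self.metab_config
        if mc.n_planted > len(AMINO_ACIDS):
            raise ValueError("n_planted exceeds the number of amino-acid features")
        if mc.n_features < len(AMINO_ACIDS):
            raise ValueError("metabolome must include the amino-acid panel")

    @property
    def n_t21(self) -> int:
        return int(sum(self.subtype_sizes))

    @property
    def stability_map(self) -> dict:
        return dict(self.stability_rho)


@dataclass
class MultiOmicsCohort:
    """All generated layers, sample metadata, planted truth, revisit layers."""

    layers: dict
    samples: pd.DataFrame
    feature_truth: dict
    visits: dict = field(default_factory=dict)
    config: SimConfig | None = None

    def validate(self) -> None:
        sample_ids = list(self.samples.index)
        for name, layer in self.layers.items():
            if list(layer.sample_ids) != sample_ids:
                raise AssertionError(f"layer {name!r} sample axis mismatch")
        frac = self.layers["cell_fractions"].values
        sums = frac.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError("cell fractions do not sum to 1 per sample")
        t21 = self.samples["karyotype"] == "T21"
        if not self.samples.loc[t21, "subtype_true"].isin(SUBTYPES).all():
            raise AssertionError("truth labels do not cover all T21 samples")

    @property
    def t21_ids(self) -> list:
        return list(self.samples.index[self.samples["karyotype"] == "T21"])

    @property
    def control_ids(self) -> list:
        return list(self.samples.index[self.samples["karyotype"] == "D21"])


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named substream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def simulate_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample metadata: karyotype, truth subtype, age, sex, source, visit."""
    ids = [f"D21_{i + 1:04d}" for i in range(config.n_controls)]
    karyotype = ["D21"] * config.n_controls
    subtype = ["D21"] * config.n_controls
    for label, size in zip(SUBTYPES, config.subtype_sizes):
        start = len(ids) - config.n_controls
        ids += [f"T21_{start + i + 1:04d}" for i in range(size)]
        karyotype += ["T21"] * size
        subtype += [label] * size
    n = len(ids)
    table = pd.DataFrame({
        "karyotype": karyotype,
        "subtype_true": subtype,
        "age": rng.uniform(6.0, 57.0, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "source": rng.choice(["A", "B"], size=n),
        "visit": 1,
    }, index=pd.Index(ids, name="sample_id"))
    return table


def _covariate_signal(samples: pd.DataFrame, eff: CovariateEffects,
                      rng: np.random.Generator, n_features: int) -> np.ndarray:
    """Per-feature covariate contributions (features x samples, log2)."""
    age = samples["age"].to_numpy(float) - samples["age"].mean()
    male = (samples["sex"] == "M").to_numpy(float)
    src_b = (samples["source"] == "B").to_numpy(float)
    # each feature responds with its own (signed) susceptibility
    a = rng.normal(eff.age_slope, abs(eff.age_slope) / 2, size=n_features)
    s = rng.normal(eff.sex_offset, abs(eff.sex_offset) / 2, size=n_features)
    b = rng.normal(eff.source_offset, abs(eff.source_offset) / 2, size=n_features)
    return a[:, None] * age[None, :] + s[:, None] * male[None, :] + b[:, None] * src_b[None, :]


def _subtype_matrix(samples: pd.DataFrame, shifts: tuple) -> np.ndarray:
    """Per-sample shift vector given (MS1, MS2, MS3) values; 0 for controls."""
    out = np.zeros(len(samples))
    for label, val in zip(SUBTYPES, shifts):
        out[(samples["subtype_true"] == label).to_numpy()] = val
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _gene_ids(config: SimConfig) -> tuple[list, list, list]:
    tc = config.transporter_config
    hsa21 = [f"HSA21G{i + 1:03d}" for i in range(config.n_hsa21_coding)]
    transporters = ([f"TRANSP_U{i + 1:02d}" for i in range(tc.n_up)]
                    + [f"TRANSP_D{i + 1:02d}" for i in range(tc.n_down)]
                    + [f"TRANSP_N{i + 1:02d}" for i in range(tc.n_neutral)])
    background = [f"BG{i + 1:05d}" for i in range(config.n_background_genes)]
    return hsa21, transporters, background


def simulate_expression(config: SimConfig, rng: np.random.Generator,
                        samples: pd.DataFrame) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Whole-blood expression on a positive RPKM-like scale plus gene truth.

    log2 model: baseline + dosage (T21, chr21 genes) + subtype x cluster
    modifier + shared latent factor (loading positively on cluster 1 and
    negatively on cluster 2) + covariate effects + noise.
    """
    hsa21, transporters, background = _gene_ids(config)
    genes = hsa21 + transporters + background
    G, n = len(genes), len(samples)
    t21 = (samples["karyotype"] == "T21").to_numpy(float)

    c1, c2 = config.gene_cluster_sizes
    cluster = np.zeros(G, dtype=int)
    cluster[:c1] = 1
    cluster[c1:c1 + c2] = 2

    baseline = rng.uniform(4.0, 12.0, size=G)
    dosage = np.zeros(G)
    jitter = rng.normal(0.0, config.dosage_gene_sd, size=config.n_hsa21_coding)
    # dosage_log2fc is the cohort-mean log2 dosage across chr21 genes; the
    # per-gene jitter is centred so that mean is planted exactly
    dosage[:config.n_hsa21_coding] = config.dosage_log2fc + jitter - jitter.mean()

    jit = config.effect_jitter
    mult = rng.uniform(1.0 - jit, 1.0 + jit, size=G)
    loading = np.zeros(G)
    lo, hi = config.latent_gene_range
    mags = config.latent_loading * rng.uniform(lo, hi, size=G)
    loading[cluster == 1] = mags[cluster == 1]
    loading[cluster == 2] = -mags[cluster == 2]

    # per-gene, per-subtype total modifiers: the graded cluster effect plus a
    # subtype-specific fingerprint offset for every chr21 gene (each subtype
    # must have a multi-gene signature of its own, not just a position along
    # the shared cluster-1/cluster-2 gradient)
    eff = np.zeros((G, len(SUBTYPES)))
    eff[cluster == 1] = np.outer(mult[cluster == 1], config.cluster1_effects)
    eff[cluster == 2] = np.outer(mult[cluster == 2], config.cluster2_effects)
    is_hsa21 = np.arange(G) < config.n_hsa21_coding
    profile = rng.normal(0.0, config.subtype_profile_sd,
                         size=(config.n_hsa21_coding, len(SUBTYPES)))
    # clipped at 1.5 SD so a fingerprint can never overwhelm a gene's cluster
    # pattern, and centred per gene so the fingerprints redistribute expression
    # across subtypes without moving the cohort-wide trisomic mean (keeping
    # the planted dosage ratio intact)
    clip = 1.5 * config.subtype_profile_sd
    profile = np.clip(profile, -clip, clip)
    weights = np.asarray(config.subtype_sizes, float) / config.n_t21
    profile -= (profile @ weights)[:, None]
    eff[is_hsa21] += profile

    # transporter panel: planted MS3-vs-MS1 regulation
    tc = config.transporter_config
    t_dir = np.array(["none"] * G, dtype=object)
    offset = config.n_hsa21_coding
    up_idx = np.arange(offset, offset + tc.n_up)
    down_idx = np.arange(offset + tc.n_up, offset + tc.n_up + tc.n_down)
    t_dir[up_idx] = "up"
    t_dir[down_idx] = "down"
    t_dir[offset + tc.n_up + tc.n_down:
          offset + tc.n_up + tc.n_down + tc.n_neutral] = "neutral"
    eff[up_idx] += np.outer(mult[up_idx], tc.up_shifts)
    eff[down_idx] += np.outer(mult[down_idx], tc.down_shifts)

    onehot = np.stack([(samples["subtype_true"] == lab).to_numpy(float)
                       for lab in SUBTYPES])
    factor = rng.normal(0.0, 1.0, size=n)

    log2x = baseline[:, None] + dosage[:, None] * t21[None, :]
    log2x += eff @ onehot
    log2x += loading[:, None] * factor[None, :]
    log2x += _covariate_signal(samples, config.covariate_effects, rng, G)
    log2x += rng.normal(0.0, config.noise_sd, size=(G, n))

    values = pd.DataFrame(np.exp2(log2x), index=pd.Index(genes, name="gene_id"),
                          columns=samples.index)
    truth = pd.DataFrame({
        "chromosome": ["21"] * config.n_hsa21_coding + ["other"] * (G - config.n_hsa21_coding),
        "coding": True,
        "cluster": cluster,
        "dosage_log2fc": dosage,
        "effect_multiplier": mult,
        "latent_loading": loading,
        "transporter": t_dir,
        "effect_MS1": eff[:, 0],
        "effect_MS2": eff[:, 1],
        "effect_MS3": eff[:, 2],
    }, index=values.index)
    return OmicsMatrix(values, "expression", "rpkm-like"), truth


# ---------------------------------------------------------------------------
# targeted cytokines and broad proteome
# ---------------------------------------------------------------------------

def simulate_panels(config: SimConfig, rng: np.random.Generator,
                    samples: pd.DataFrame) -> tuple[OmicsMatrix, OmicsMatrix, dict]:
    """Targeted cytokine concentrations and broad plasma proteome.

    Log-normal analytes; the seven score analytes carry an MS3 z-shift well
    above the MS1/MS2 shift, and the acute-phase proteins of the broad panel
    carry the shifts that drive the ratio classifiers.
    """
    pc = config.panel_config
    msd_named = list(SCORE_ANALYTES) + list(pc.shared_analytes) + list(pc.ms1_analytes)
    if len(set(msd_named)) != len(msd_named):
        raise ValueError("duplicate analyte names in panel configuration")
    fillers = [f"MSD{i + 1:02d}" for i in range(pc.n_msd - len(msd_named))]
    msd_ids = msd_named + fillers

    n = len(samples)
    sd = pc.msd_noise_sd
    shifts = np.zeros((len(msd_ids), n))
    score_shift = _subtype_matrix(samples, (pc.score_other_shift, pc.score_other_shift,
                                            pc.score_ms3_shift))
    shared = _subtype_matrix(samples, (pc.shared_shift,) * 3)
    ms1_only = _subtype_matrix(samples, (pc.ms1_shift, 0.0, 0.0))
    for i, a in enumerate(msd_ids):
        if a in SCORE_ANALYTES:
            shifts[i] = score_shift * sd
        elif a in pc.shared_analytes:
            shifts[i] = shared * sd
        elif a in pc.ms1_analytes:
            shifts[i] = ms1_only * sd

    base = rng.uniform(-2.0, 8.0, size=len(msd_ids))  # log2 pg/mL
    log2x = base[:, None] + shifts
    log2x += _covariate_signal(samples, config.covariate_effects, rng, len(msd_ids))
    log2x += rng.normal(0.0, sd, size=(len(msd_ids), n))
    msd = OmicsMatrix(pd.DataFrame(np.exp2(log2x), index=pd.Index(msd_ids, name="analyte"),
                                   columns=samples.index), "msd_panel", "pg/mL")
    msd_truth = pd.DataFrame({
        "score_analyte": [a in SCORE_ANALYTES for a in msd_ids],
        "ms3_z_shift": [pc.score_ms3_shift if a in SCORE_ANALYTES
                        else (pc.shared_shift if a in pc.shared_analytes else 0.0)
                        for a in msd_ids],
    }, index=msd.feature_ids)

    soma_named = list(ACUTE_PHASE_PROTEINS)
    soma_ids = soma_named + [f"SOMA{i + 1:03d}" for i in range(pc.n_soma - len(soma_named))]
    ssd = pc.soma_noise_sd
    acute = _subtype_matrix(samples, (pc.soma_other_shift, pc.soma_other_shift,
                                      pc.soma_ms3_shift))
    sshift = np.zeros((len(soma_ids), n))
    for i, a in enumerate(soma_ids):
        if a in ACUTE_PHASE_PROTEINS:
            sshift[i] = acute * ssd
    sbase = rng.uniform(6.0, 14.0, size=len(soma_ids))  # log2 relative abundance
    slog2 = sbase[:, None] + sshift
    slog2 += _covariate_signal(samples, config.covariate_effects, rng, len(soma_ids))
    slog2 += rng.normal(0.0, ssd, size=(len(soma_ids), n))
    soma = OmicsMatrix(pd.DataFrame(np.exp2(slog2), index=pd.Index(soma_ids, name="analyte"),
                                    columns=samples.index), "somalike_proteome",
                       "relative abundance")
    soma_truth = pd.DataFrame({
        "acute_phase": [a in ACUTE_PHASE_PROTEINS for a in soma_ids],
        "ms3_z_shift": [pc.soma_ms3_shift if a in ACUTE_PHASE_PROTEINS else 0.0
                        for a in soma_ids],
    }, index=soma.feature_ids)

    return msd, soma, {"msd_panel": msd_truth, "somalike_proteome": soma_truth}


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

def simulate_metabolome(config: SimConfig, rng: np.random.Generator,
                        samples: pd.DataFrame) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Peak-intensity metabolome with graded amino-acid depletion.

    Exactly ``metab_config.n_planted`` analytes carry an extra (graded,
    strongest in MS3) depletion on top of the shared T21 amino-acid effect;
    a configurable fraction of intensities is zeroed to exercise zero
    replacement, and a per-sample scale factor exercises median
    normalisation.
    """
    mc = config.metab_config
    planted = list(DEPLETED_ANALYTES[:mc.n_planted])
    others = [f"MET{i + 1:03d}" for i in range(mc.n_features - len(AMINO_ACIDS))]
    ids = list(AMINO_ACIDS) + others
    n = len(samples)
    t21 = (samples["karyotype"] == "T21").to_numpy(float)

    base = rng.uniform(14.0, 22.0, size=len(ids))
    log2x = base[:, None] + np.zeros((len(ids), n))
    graded = _subtype_matrix(samples, mc.planted_shifts)
    for i, a in enumerate(ids):
        if a in AMINO_ACIDS:
            log2x[i] += mc.t21_aa_shift * t21
        if a in planted:
            log2x[i] += graded
    log2x += _covariate_signal(samples, config.covariate_effects, rng, len(ids))
    log2x += rng.normal(0.0, mc.noise_sd, size=(len(ids), n))
    log2x += rng.normal(0.0, mc.sample_scale_sd, size=n)[None, :]  # loading differences

    values = np.exp2(log2x)
    if mc.zero_rate > 0:
        zeros = rng.random(values.shape) < mc.zero_rate
        values[zeros] = 0.0

    truth = pd.DataFrame({
        "amino_acid": [a in AMINO_ACIDS for a in ids],
        "planted_depletion": [a in planted for a in ids],
        "ms3_vs_ms1_log2fc": [mc.planted_shifts[2] - mc.planted_shifts[0]
                              if a in planted else 0.0 for a in ids],
    }, index=pd.Index(ids, name="analyte"))
    m = OmicsMatrix(pd.DataFrame(values, index=truth.index, columns=samples.index),
                    "metabolome", "intensity")
    return m, truth


# ---------------------------------------------------------------------------
# immune-cell composition and CBC
# ---------------------------------------------------------------------------

def simulate_cells_and_cbc(config: SimConfig, rng: np.random.Generator,
                           samples: pd.DataFrame) -> tuple[OmicsMatrix, OmicsMatrix, dict]:
    """Logistic-normal cell fractions plus a CBC layer with matching shifts."""
    cc = config.cell_config
    n = len(samples)
    if len(CELL_TYPES) < 2:
        raise ValueError("need at least 2 composition categories")

    logit = np.log(np.asarray(cc.base_fractions, float))[:, None] + np.zeros((len(CELL_TYPES), n))
    neutro = _subtype_matrix(samples, cc.neutro_shifts) * cc.noise_sd
    lymph = _subtype_matrix(samples, cc.lymph_shifts) * cc.noise_sd
    for i, ct in enumerate(CELL_TYPES):
        if ct == "neutrophils":
            logit[i] += neutro
        elif ct in ("t_cells", "b_cells", "nk_cells"):
            logit[i] += lymph
    logit += rng.normal(0.0, cc.noise_sd, size=logit.shape)
    expd = np.exp(logit)
    fractions = expd / expd.sum(axis=0, keepdims=True)
    cells = OmicsMatrix(pd.DataFrame(fractions, index=pd.Index(CELL_TYPES, name="cell_type"),
                                     columns=samples.index), "cell_fractions", "fraction")

    sd = cc.cbc_noise_sd
    t21 = (samples["karyotype"] == "T21").to_numpy(float)
    lymph_shift = _subtype_matrix(samples, cc.cbc_lymph_shifts) * sd
    neutro_shift = _subtype_matrix(samples, cc.cbc_neutro_shifts) * sd
    baselines = {"wbc": np.log2(7.0), "rbc": np.log2(4.6), "hemoglobin": np.log2(13.5),
                 "hematocrit": np.log2(40.0), "mcv": np.log2(88.0), "mch": np.log2(29.0),
                 "platelets": np.log2(250.0), "abs_lymphocytes": np.log2(2.0),
                 "pct_lymphocytes": np.log2(30.0), "abs_neutrophils": np.log2(4.0),
                 "pct_neutrophils": np.log2(55.0)}
    log2x = np.zeros((len(CBC_FEATURES), n))
    for i, feat in enumerate(CBC_FEATURES):
        log2x[i] = baselines[feat]
        if feat in ("abs_lymphocytes", "pct_lymphocytes"):
            log2x[i] += lymph_shift
        elif feat in ("abs_neutrophils", "pct_neutrophils"):
            log2x[i] += neutro_shift
        elif feat == "mcv":
            log2x[i] += cc.mcv_t21_shift * sd * t21
    log2x += _covariate_signal(samples, config.covariate_effects, rng, len(CBC_FEATURES))
    # CBC noise is milder than omics layers
    log2x += rng.normal(0.0, sd, size=log2x.shape)
    cbc = OmicsMatrix(pd.DataFrame(np.exp2(log2x), index=pd.Index(CBC_FEATURES, name="parameter"),
                                   columns=samples.index), "cbc", "mixed clinical units")

    truth = {
        "cell_fractions": pd.DataFrame({
            "ms3_shift_sd": [cc.neutro_shifts[2] if c == "neutrophils"
                             else (cc.lymph_shifts[2] if c in ("t_cells", "b_cells", "nk_cells")
                                   else 0.0) for c in CELL_TYPES]}, index=cells.feature_ids),
        "cbc": pd.DataFrame({
            "ms3_shift_sd": [cc.cbc_lymph_shifts[2] if f in ("abs_lymphocytes", "pct_lymphocytes")
                             else (cc.cbc_neutro_shifts[2] if f in ("abs_neutrophils",
                                                                    "pct_neutrophils") else 0.0)
                             for f in CBC_FEATURES]}, index=cbc.feature_ids),
    }
    return cells, cbc, truth


# ---------------------------------------------------------------------------
# longitudinal revisit
# ---------------------------------------------------------------------------

def simulate_revisit(layer: OmicsMatrix, stability_rho, rng: np.random.Generator,
                     sample_ids=None, score_analytes=SCORE_ANALYTES) -> OmicsMatrix:
    """Second-visit measurements with analyte-specific stability.

    Per analyte, visit-2 = mean + sd * (rho * z1 + sqrt(1 - rho^2) * eps) on
    the log2 scale, back-transformed; the expected inter-visit correlation
    approximates the requested rho.  ``stability_rho`` is a scalar or a
    mapping with analyte overrides plus "default"/"score" entries.
    """
    if sample_ids is None:
        sample_ids = list(layer.sample_ids)
    sub = layer.values[list(sample_ids)]
    log2v = np.log2(sub.to_numpy(float))
    mean = log2v.mean(axis=1, keepdims=True)
    sd = log2v.std(axis=1, ddof=1, keepdims=True)

    def rho_for(analyte: str) -> float:
        if np.isscalar(stability_rho):
            r = float(stability_rho)
        else:
            mapping = dict(stability_rho)
            if analyte in mapping:
                r = float(mapping[analyte])
            elif analyte in score_analytes and "score" in mapping:
                r = float(mapping["score"])
            else:
                r = float(mapping.get("default", 0.5))
        if not (-1.0 <= r <= 1.0):
            raise ValueError(f"stability rho for {analyte!r} outside [-1, 1]")
        return r

    rhos = np.array([rho_for(a) for a in sub.index])[:, None]
    z1 = np.where(sd > 0, (log2v - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    eps = rng.normal(0.0, 1.0, size=log2v.shape)
    z2 = rhos * z1 + np.sqrt(1.0 - rhos ** 2) * eps
    v2 = np.exp2(mean + sd * z2)
    return OmicsMatrix(pd.DataFrame(v2, index=sub.index, columns=sub.columns),
                       layer.layer + "_visit2", layer.units)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> MultiOmicsCohort:
    """Generate the full multiomics cohort (all layers + truth + revisits)."""
    if config is None:
        config = SimConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    s = config.seed

    samples = simulate_samples(config, substream(s, "samples"))
    expr, expr_truth = simulate_expression(config, substream(s, "expression"), samples)
    msd, soma, panel_truth = simulate_panels(config, substream(s, "panels"), samples)
    metab, metab_truth = simulate_metabolome(config, substream(s, "metabolome"), samples)
    cells, cbc, cell_truth = simulate_cells_and_cbc(config, substream(s, "cells"), samples)

    layers = {"expression": expr, "msd_panel": msd, "somalike_proteome": soma,
              "metabolome": metab, "cell_fractions": cells, "cbc": cbc}
    truth = {"expression": expr_truth, "metabolome": metab_truth,
             **panel_truth, **cell_truth}

    t21_ids = list(samples.index[samples["karyotype"] == "T21"])
    rng_rv = substream(s, "revisit")
    revisit_ids = sorted(rng_rv.choice(t21_ids, size=min(config.n_revisit, len(t21_ids)),
                                       replace=False))
    visits = {
        "msd_panel": simulate_revisit(msd, config.stability_map, rng_rv, revisit_ids),
        "cbc": simulate_revisit(cbc, config.stability_map, rng_rv, revisit_ids),
    }

    cohort = MultiOmicsCohort(layers=layers, samples=samples, feature_truth=truth,
                              visits=visits, config=config)
    cohort.validate()
    return cohort
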