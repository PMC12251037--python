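"""Synthetic hyperhomocysteinemia cohorts with known ground truth.

Generates every input the analysis pipeline consumes — the paired clinical
table, LINE-1 pyrosequencing percentages, CpG-by-sample beta matrices, a
MAF-like variant table with a gene-panel BED and a ClinVar-style annotation
TSV — with the statistical structure the downstream stages assume, so that
each stage can be tested against planted truth without any external data.

Design notes
------------
* Group membership is planted, not emergent: responder pairs are redrawn
  until HCY_after < HCY_before (and the converse for non-responders), so
  sign-based stratification recovers the planted labels exactly.
* Positive biomarkers (HCY, folate, cfDNA) are drawn from correlated
  lognormals whose parameters are moment-matched to the configured
  mean/SD, keeping values positive without truncation bias and making
  per-patient relative changes well behaved.
* Non-responder biological-age deltas are generated *from* the planted
  burden-delta regression line (delta = mean + slope * (burden - mean
  burden) + noise), which makes the planted group mean, the regression
  line, and the burden correlation mutually consistent.
* Planted shared variants have fixed carrier sets (the first k patients of
  each group); background variants get patient-unique positions, so no
  background variant can ever reach a carrier-frequency threshold.
* One integer seed drives everything through a spawned SeedSequence tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import age_transform
from .stratification import NON_RESPONDER, RESPONDER
from .variants import PanelRegion, VariantRecord, write_variants

# --------------------------------------------------------------------------
# gene panel, pathways and planted variants

#: 29 one-carbon-metabolism genes plus 12 further panel genes (41 total)
ONE_CARBON_GENES = [
    "AHCY", "ATIC", "BHMT", "BHMT2", "CBS", "CHAT", "CHDH", "CHKA", "CTH",
    "DHFR", "DNMT1", "DNMT3A", "DNMT3B", "FOLR1", "FOLR2", "FPGS", "GART",
    "GGH", "MTHFD1", "MTHFD1L", "MTHFD2", "MTHFR", "MTR", "MTRR", "PEMT",
    "SHMT1", "SHMT2", "SLC19A1", "TYMS",
]
EXTRA_PANEL_GENES = [
    "ALDH1L1", "CCT3", "DTHD1", "GNMT", "HIF3A", "MAT1A", "MAT2A", "PIPOX",
    "PLD2", "PRMT3", "SARDH", "TBC1D1",
]
PANEL_GENES = sorted(ONE_CARBON_GENES + EXTRA_PANEL_GENES)

PATHWAYS = (
    "transferring one-carbon groups",
    "folate cycle",
    "folate biosynthesis",
    "methionine cycle",
    "cysteine and methionine metabolism",
    "glycine, serine and threonine metabolism",
)


def default_pathway_map() -> dict[str, list[str]]:
    """Gene -> folate-related pathway membership (1-2 pathways per gene)."""
    m = {
        "MTHFR": ["folate cycle", "methionine cycle"],
        "MTR": ["methionine cycle"],
        "MTRR": ["methionine cycle"],
        "MTHFD1": ["folate cycle"],
        "MTHFD1L": ["folate cycle"],
        "MTHFD2": ["folate cycle"],
        "TYMS": ["methionine cycle", "folate cycle"],
        "DHFR": ["folate biosynthesis", "folate cycle"],
        "FPGS": ["folate biosynthesis"],
        "GGH": ["folate biosynthesis"],
        "FOLR1": ["folate biosynthesis"],
        "FOLR2": ["folate biosynthesis"],
        "SLC19A1": ["folate biosynthesis"],
        "DNMT1": ["methionine cycle"],
        "DNMT3A": ["methionine cycle"],
        "DNMT3B": ["methionine cycle"],
        "AHCY": ["methionine cycle", "cysteine and methionine metabolism"],
        "MAT1A": ["methionine cycle", "cysteine and methionine metabolism"],
        "MAT2A": ["methionine cycle", "cysteine and methionine metabolism"],
        "CBS": ["cysteine and methionine metabolism"],
        "CTH": ["cysteine and methionine metabolism"],
        "BHMT": ["methionine cycle", "glycine, serine and threonine metabolism"],
        "BHMT2": ["methionine cycle"],
        "PEMT": ["methionine cycle"],
        "CHDH": ["glycine, serine and threonine metabolism"],
        "CHKA": ["glycine, serine and threonine metabolism"],
        "CHAT": ["glycine, serine and threonine metabolism"],
        "SHMT1": ["folate cycle", "glycine, serine and threonine metabolism"],
        "SHMT2": ["folate cycle", "glycine, serine and threonine metabolism"],
        "GART": ["transferring one-carbon groups"],
        "ATIC": ["transferring one-carbon groups"],
        "GNMT": ["transferring one-carbon groups", "methionine cycle"],
        "PRMT3": ["transferring one-carbon groups", "methionine cycle"],
        "SARDH": ["glycine, serine and threonine metabolism"],
        "PIPOX": ["glycine, serine and threonine metabolism"],
        "ALDH1L1": ["folate cycle"],
        "HIF3A": ["methionine cycle"],
        "CCT3": ["transferring one-carbon groups"],
        "TBC1D1": ["transferring one-carbon groups"],
        "DTHD1": ["transferring one-carbon groups"],
        "PLD2": ["glycine, serine and threonine metabolism"],
    }
    assert set(m) == set(PANEL_GENES)
    return m


def default_panel() -> list[PanelRegion]:
    """Synthetic loci for the 41 panel genes (deterministic coordinates)."""
    regions = []
    for i, gene in enumerate(PANEL_GENES):
        chrom = str((i % 22) + 1)
        start = 1_000_000 * (i + 1)
        regions.append(PanelRegion(chrom, start, start + 50_000, gene))
    return regions


_GENE_REGION = {r.gene: r for r in default_panel()}


@dataclass(frozen=True)
class PlantedVariant:
    """A shared variant with fixed per-group carrier counts.

    Carriers are the first ``carriers_responder`` / ``carriers_nonresponder``
    patients of each group, so planted frequencies are recovered exactly.
    """

    gene: str
    hgvs_label: str
    carriers_responder: int
    carriers_nonresponder: int
    significance: str = ""  # empty -> left unclassified
    classification: str = "missense"
    ref: str = "C"
    alt: str = "T"
    offset: int = 101  # 1-based offset into the gene's panel region

    @property
    def region(self) -> PanelRegion:
        return _GENE_REGION[self.gene]

    @property
    def pos(self) -> int:
        return self.region.start + self.offset

    @property
    def variant_key(self) -> str:
        return f"{self.region.chrom}:{self.pos}:{self.ref}:{self.alt}"


def default_planted_variants() -> list[PlantedVariant]:
    """The planted frequency structure of the default study conditions.

    Four dual-threshold hotspots (HIF3A, TYMS, DNMT3A, PRMT3), the two
    classic MTHFR polymorphisms at their observed group frequencies, and
    one MTRR variant that reaches the graph-node threshold only.
    """
    return [
        PlantedVariant("HIF3A", "n.*1977A > G", 1, 21, "risk factor", "other", "A", "G", 1977),
        PlantedVariant("TYMS", "c.*89A > G", 7, 18, "Uncertain significance", "other", "A", "G", 89),
        PlantedVariant("DNMT3A", "c.178072C > T", 9, 18, "Uncertain significance", "missense", "C", "T", 2072),
        PlantedVariant("PRMT3", "c.993+10967G > A", 8, 16, "Uncertain significance", "other", "G", "A", 10967),
        PlantedVariant("MTHFR", "c.665C > T (C677T)", 14, 14, "Pathogenic", "missense", "C", "T", 665),
        PlantedVariant("MTHFR", "c.1286A > C (A1298C)", 8, 9, "risk factor", "missense", "A", "C", 1286),
        PlantedVariant("MTRR", "c.66A > G", 12, 12, "risk factor", "missense", "A", "G", 66),
    ]


#: per-gene Poisson rates of patient-unique background variants, per group
BACKGROUND_RATES = {
    RESPONDER: {
        "MTHFD1L": 0.90, "TBC1D1": 0.80, "MTRR": 0.65, "DTHD1": 0.60,
        "CHAT": 0.60, "GART": 0.50, "PLD2": 0.45, "MTHFD1": 0.30,
        "PEMT": 0.30, "CBS": 0.25, "MTR": 0.25, "TYMS": 0.20, "DNMT3B": 0.20,
        "SHMT1": 0.15,
    },
    NON_RESPONDER: {
        "MTHFD1": 0.85, "CHAT": 0.80, "PEMT": 0.70, "MTRR": 0.60,
        "MTHFD1L": 0.55, "GART": 0.40, "TBC1D1": 0.35, "DTHD1": 0.30,
        "CBS": 0.25, "MTR": 0.25, "TYMS": 0.20, "DNMT3B": 0.20,
    },
}

#: sampling weights of background classifications / SNV classes
_BG_CLASSES = [
    ("missense", 0.55), ("in_frame_del", 0.12), ("frame_shift_del", 0.08),
    ("nonsense", 0.07), ("silent", 0.08), ("splice_site", 0.04),
    ("frame_shift_ins", 0.03), ("in_frame_ins", 0.03),
]
_SNV_WEIGHTS = [("C>T", 0.34), ("T>C", 0.27), ("C>G", 0.16), ("C>A", 0.10),
                ("T>A", 0.07), ("T>G", 0.06)]


# --------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Study conditions of the emulated cohort (defaults follow the study).

    All concentrations are configured as mean/SD on the measurement scale
    (HCY in umol/L, folate in nmol/L, cfDNA in ng/mL); the generator
    moment-matches lognormals to them.
    """

    n_responders: int = 21
    n_nonresponders: int = 22

    # HCY: per-group baselines, with a shared fallback used when None
    hcy_baseline_mean: float = 16.3
    hcy_baseline_sd: float = 4.8
    responder_hcy_baseline_mean: float | None = 15.7
    responder_hcy_baseline_sd: float | None = 5.5
    nonresponder_hcy_baseline_mean: float | None = 16.7
    nonresponder_hcy_baseline_sd: float | None = 4.1
    responder_hcy_after_mean: float = 11.0
    responder_hcy_after_sd: float = 2.9
    nonresponder_hcy_after_mean: float = 19.6
    nonresponder_hcy_after_sd: float = 3.7
    hcy_pair_corr: float = 0.9

    folate_before_mean: float = 46.3
    folate_before_sd: float = 40.0
    folate_after_mean: float = 81.4
    folate_after_sd: float = 29.4
    folate_pair_corr: float = 0.5

    cfdna_before_mean: float = 9.0
    cfdna_before_sd: float = 4.8
    cfdna_after_mean: float = 8.1
    cfdna_after_sd: float = 4.9
    cfdna_pair_corr: float = 0.9
    cfdna_hcy_corr: float = 0.24  # pooled HCY-cfDNA correlation to emulate

    # LINE-1 (percent methylation); effect = points added post-supplementation
    line1_baseline_means: dict = field(default_factory=lambda: {
        "cfDNA": (85.0, 75.4, 75.9),
        "granulocyte": (84.2, 74.5, 74.8),
        "mononuclear": (81.4, 74.0, 73.5),
    })
    line1_effect: dict = field(default_factory=lambda: {
        "cfDNA": 1.5, "granulocyte": 0.0, "mononuclear": 1.45,
    })
    line1_patient_sd: float = 2.5
    line1_noise_sd: float = 1.0

    # chronological ages (mostly postmenopausal cohort)
    age_mean: float = 62.0
    age_sd: float = 10.0
    age_min: float = 35.0
    age_max: float = 90.0

    # biological-age deltas (years, post - baseline)
    age_delta_responder_mean: float = -0.5
    age_delta_responder_sd: float = 4.7
    age_delta_nonresponder_mean: float = -5.3
    # non-responder deltas are driven by the planted burden association:
    # delta = mean + slope * (burden - burden_mean) + N(0, noise_sd)
    assoc_gene: str = "CCT3"
    assoc_slope: float = 0.394
    assoc_burden_mean: float = 9.934
    assoc_burden_sd: float = 7.2
    assoc_noise_sd: float = 5.9

    # clock / beta matrices
    clock_cpg_count: int = 308
    clock_signal_count: int = 272
    noise_cpg_count: int = 42
    noise_sd: float = 0.02
    clock_train_n: int = 200
    adult_age: float = 20.0
    bioage_baseline_sd: float = 2.0  # true bioage scatter around chron. age

    planted_variants: list = field(default_factory=default_planted_variants)
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return self.n_responders + self.n_nonresponders

    def validate(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ValueError("group sizes must be non-negative")
        for name, value in vars(self).items():
            if name.endswith("_sd") and value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative")
        for pv in self.planted_variants:
            if pv.carriers_responder > self.n_responders:
                raise ValueError(
                    f"{pv.gene} {pv.hgvs_label}: responder carrier count "
                    f"{pv.carriers_responder} exceeds group size {self.n_responders}"
                )
            if pv.carriers_nonresponder > self.n_nonresponders:
                raise ValueError(
                    f"{pv.gene} {pv.hgvs_label}: non-responder carrier count "
                    f"{pv.carriers_nonresponder} exceeds group size {self.n_nonresponders}"
                )


# --------------------------------------------------------------------------
# generative methylome and beta matrices

@dataclass
class AgingMethylome:
    """Generative age->beta model: beta_i = baseline_i + slope_i * F(age).

    Slopes are in beta units per transformed-age unit; CpGs with zero slope
    carry no age signal. This is the data-generating counterpart of the
    predictive clock (which maps betas back to transformed age).
    """

    cpg_ids: list[str]
    baseline: np.ndarray
    slope: np.ndarray
    adult_age: float = 20.0

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if not len(self.cpg_ids) == len(self.baseline) == len(self.slope):
            raise ValueError("cpg_ids, baseline and slope must align")


def random_methylome(
    n_cpgs: int = 308,
    n_signal: int = 272,
    seed: int = 0,
    adult_age: float = 20.0,
) -> AgingMethylome:
    """Draw a random aging methylome with ``n_signal`` age-coupled CpGs.

    Baselines are uniform in [0.3, 0.7] and slope magnitudes uniform in
    [0.01, 0.05] with random sign, which keeps noiseless betas inside
    [0, 1] for ages up to ~120 (no clipping distortion of the signal).
    """
    if n_signal > n_cpgs:
        raise ValueError("n_signal cannot exceed n_cpgs")
    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:08d}" for i in range(n_cpgs)]
    baseline = rng.uniform(0.3, 0.7, n_cpgs)
    slope = np.zeros(n_cpgs)
    magnitude = rng.uniform(0.01, 0.05, n_signal)
    sign = rng.choice([-1.0, 1.0], n_signal)
    slope[:n_signal] = magnitude * sign
    return AgingMethylome(cpg_ids, baseline, slope, adult_age)


def generate_beta_matrix(
    ages,
    true_model: AgingMethylome,
    noise_sd: float,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    n_noise_cpgs: int = 0,
) -> pd.DataFrame:
    """CpG-by-sample beta matrix from an aging methylome.

    Model CpGs are affine in transformed age plus Gaussian noise, clipped
    to [0, 1]; ``n_noise_cpgs`` extra rows are pure noise with no age
    signal (they exercise whitelist filtering downstream).
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(len(ages))]
    if len(sample_ids) != len(ages):
        raise ValueError("one sample id per age is required")
    t = age_transform(ages, true_model.adult_age)
    signal = true_model.baseline[:, None] + true_model.slope[:, None] * t[None, :]
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    rows = [np.clip(signal, 0.0, 1.0)]
    ids = list(true_model.cpg_ids)
    if n_noise_cpgs:
        noise = rng.normal(0.5, 0.15, (n_noise_cpgs, len(ages)))
        rows.append(np.clip(noise, 0.0, 1.0))
        ids += [f"noise{i:05d}" for i in range(n_noise_cpgs)]
    return pd.DataFrame(np.vstack(rows), index=ids, columns=sample_ids)


# --------------------------------------------------------------------------
# lognormal biomarker machinery

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal moment matching needs a positive mean")
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _paired_lognormal(
    rng: np.random.Generator,
    n: int,
    before: tuple[float, float],
    after: tuple[float, float],
    rho: float,
    shared: np.ndarray | None = None,
    loading: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated lognormal (before, after) pairs.

    ``shared`` is an optional standard-normal patient latent entering both
    timepoints with weight ``loading`` (used to couple cfDNA with HCY).
    """
    mu_b, s_b = _lognormal_params(*before)
    mu_a, s_a = _lognormal_params(*after)
    lam = loading
    res = np.sqrt(1.0 - lam**2)
    eps_b = rng.standard_normal(n)
    eps_a = rng.standard_normal(n)
    if shared is None:
        shared = np.zeros(n)
        lam, res = 0.0, 1.0
    z_b = lam * shared + res * eps_b
    rho_t = (rho - lam**2) / (1.0 - lam**2)
    rho_t = np.clip(rho_t, -1.0, 1.0)
    z_a = lam * shared + res * (rho_t * eps_b + np.sqrt(1.0 - rho_t**2) * eps_a)
    return np.exp(mu_b + s_b * z_b), np.exp(mu_a + s_a * z_a)


def _rejection_pairs(
    rng: np.random.Generator,
    n: int,
    before: tuple[float, float],
    after: tuple[float, float],
    rho: float,
    want_decrease: bool,
    shared: np.ndarray,
    loading: float,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise rejection resampling until every pair has the planted sign."""
    b, a = _paired_lognormal(rng, n, before, after, rho, shared, loading)
    for _ in range(max_tries):
        # want_decrease: resample where a >= b; else resample where a < b
        bad = (a >= b) if want_decrease else (a < b)
        idx = np.flatnonzero(bad)
        if idx.size == 0:
            return b, a
        nb, na = _paired_lognormal(
            rng, idx.size, before, after, rho, shared[idx], loading
        )
        b[idx], a[idx] = nb, na
    raise RuntimeError("rejection resampling failed to converge")


# --------------------------------------------------------------------------
# the cohort generator

@dataclass
class CohortDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    cohort: pd.DataFrame
    line1: pd.DataFrame
    beta_before: pd.DataFrame
    beta_after: pd.DataFrame
    beta_train: pd.DataFrame
    train_ages: pd.Series
    whitelist: list[str]
    variants: list[VariantRecord]
    annotation_db: dict[str, str]
    panel: list[PanelRegion]
    pathway_map: dict[str, list[str]]
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        """Write every artifact as TSV/BED/MAF text files; returns the paths."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cohort": out / "cohort.tsv",
            "line1": out / "line1.tsv",
            "beta_before": out / "beta_before.tsv",
            "beta_after": out / "beta_after.tsv",
            "beta_train": out / "beta_train.tsv",
            "train_ages": out / "train_ages.tsv",
            "whitelist": out / "whitelist.txt",
            "variants": out / "variants.maf",
            "annotation": out / "annotation.tsv",
            "panel": out / "panel.bed",
            "pathways": out / "pathways.tsv",
        }
        self.cohort.to_csv(paths["cohort"], sep="\t", index=False, float_format="%.6f")
        self.line1.to_csv(paths["line1"], sep="\t", index=False, float_format="%.6f")
        for key in ("beta_before", "beta_after", "beta_train"):
            getattr(self, key).to_csv(
                paths[key], sep="\t", index_label="cpg_id", float_format="%.6f"
            )
        self.train_ages.rename("age_years").to_csv(
            paths["train_ages"], sep="\t", index_label="sample_id", float_format="%.6f"
        )
        Path(paths["whitelist"]).write_text("\n".join(self.whitelist) + "\n")
        write_variants(self.variants, paths["variants"])
        with open(paths["annotation"], "w") as fh:
            fh.write("variant_key\tclinical_significance\n")
            for key in sorted(self.annotation_db):
                fh.write(f"{key}\t{self.annotation_db[key]}\n")
        with open(paths["panel"], "w") as fh:
            for r in self.panel:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\n")
        with open(paths["pathways"], "w") as fh:
            fh.write("gene\tpathway\n")
            for gene in sorted(self.pathway_map):
                for pw in self.pathway_map[gene]:
                    fh.write(f"{gene}\t{pw}\n")
        return {k: str(v) for k, v in paths.items()}


def _classification_to_type(cls: str) -> str:
    if cls.endswith("_del"):
        return "DEL"
    if cls.endswith("_ins"):
        return "INS"
    return "SNP"


def generate_cohort(config: SimConfig | None = None) -> CohortDataset:
    """Generate one full synthetic cohort under the configured conditions."""
    config = config or SimConfig()
    config.validate()
    n_r, n_n = config.n_responders, config.n_nonresponders
    n = config.n_patients
    seeds = np.random.SeedSequence(config.seed).spawn(7)
    rng_bio = np.random.default_rng(seeds[0])
    rng_line1 = np.random.default_rng(seeds[1])
    rng_age = np.random.default_rng(seeds[2])
    rng_meth = seeds[3]
    rng_beta = seeds[4]
    rng_var = np.random.default_rng(seeds[5])
    rng_delta = np.random.default_rng(seeds[6])

    patient_ids = [f"HHC{i + 1:03d}" for i in range(n)]
    responders = patient_ids[:n_r]
    nonresponders = patient_ids[n_r:]
    group_truth = [RESPONDER] * n_r + [NON_RESPONDER] * n_n

    # --- paired clinical biomarkers -------------------------------------
    shared = rng_bio.standard_normal(n)  # HCY/cfDNA coupling latent
    loading = float(np.sqrt(max(config.cfdna_hcy_corr, 0.0)))
    rb_mean = (
        config.responder_hcy_baseline_mean
        if config.responder_hcy_baseline_mean is not None
        else config.hcy_baseline_mean
    )
    rb_sd = (
        config.responder_hcy_baseline_sd
        if config.responder_hcy_baseline_sd is not None
        else config.hcy_baseline_sd
    )
    nb_mean = (
        config.nonresponder_hcy_baseline_mean
        if config.nonresponder_hcy_baseline_mean is not None
        else config.hcy_baseline_mean
    )
    nb_sd = (
        config.nonresponder_hcy_baseline_sd
        if config.nonresponder_hcy_baseline_sd is not None
        else config.hcy_baseline_sd
    )
    hcy_b = np.empty(n)
    hcy_a = np.empty(n)
    if n_r:
        hcy_b[:n_r], hcy_a[:n_r] = _rejection_pairs(
            rng_bio, n_r, (rb_mean, rb_sd),
            (config.responder_hcy_after_mean, config.responder_hcy_after_sd),
            config.hcy_pair_corr, True, shared[:n_r], loading,
        )
    if n_n:
        hcy_b[n_r:], hcy_a[n_r:] = _rejection_pairs(
            rng_bio, n_n, (nb_mean, nb_sd),
            (config.nonresponder_hcy_after_mean, config.nonresponder_hcy_after_sd),
            config.hcy_pair_corr, False, shared[n_r:], loading,
        )
    folate_b, folate_a = _paired_lognormal(
        rng_bio, n, (config.folate_before_mean, config.folate_before_sd),
        (config.folate_after_mean, config.folate_after_sd), config.folate_pair_corr,
    )
    cfdna_b, cfdna_a = _paired_lognormal(
        rng_bio, n, (config.cfdna_before_mean, config.cfdna_before_sd),
        (config.cfdna_after_mean, config.cfdna_after_sd), config.cfdna_pair_corr,
        shared, loading,
    )

    ages = np.clip(
        rng_age.normal(config.age_mean, config.age_sd, n),
        config.age_min, config.age_max,
    )
    sex = rng_age.choice(["F", "M"], n, p=[0.7, 0.3])

    cohort = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "group_truth": group_truth,
            "age_years": ages,
            "sex": sex,
            "hcy_before": hcy_b,
            "hcy_after": hcy_a,
            "folate_before": folate_b,
            "folate_after": folate_a,
            "cfdna_before": cfdna_b,
            "cfdna_after": cfdna_a,
        }
    )

    # --- LINE-1 pyrosequencing ------------------------------------------
    line1_rows = []
    for fraction, cpg_means in config.line1_baseline_means.items():
        effect = config.line1_effect.get(fraction, 0.0)
        latent = rng_line1.normal(0.0, config.line1_patient_sd, n)
        for tp, shift in (("baseline", 0.0), ("post", effect)):
            noise = rng_line1.normal(0.0, config.line1_noise_sd, (n, 3))
            for i, pid in enumerate(patient_ids):
                vals = np.clip(
                    np.asarray(cpg_means) + latent[i] + shift + noise[i], 0.0, 100.0
                )
                line1_rows.append(
                    {
                        "patient_id": pid, "fraction": fraction, "timepoint": tp,
                        "cpg1": vals[0], "cpg2": vals[1], "cpg3": vals[2],
                    }
                )
    line1 = pd.DataFrame(line1_rows)

    # --- variants --------------------------------------------------------
    variants: list[VariantRecord] = []
    annotation_db: dict[str, str] = {}
    for pv in config.planted_variants:
        carriers = (
            responders[: pv.carriers_responder]
            + nonresponders[: pv.carriers_nonresponder]
        )
        for pid in carriers:
            variants.append(
                VariantRecord(
                    patient_id=pid, gene=pv.gene, chrom=pv.region.chrom,
                    pos=pv.pos, ref=pv.ref, alt=pv.alt,
                    variant_classification=pv.classification,
                    variant_type=_classification_to_type(pv.classification)
                    if len(pv.ref) == len(pv.alt) == 1 else "DEL",
                    hgvs_label=pv.hgvs_label,
                )
            )
        if pv.significance:
            annotation_db[pv.variant_key] = pv.significance

    bg_classes, bg_weights = zip(*_BG_CLASSES)
    snv_classes, snv_weights = zip(*_SNV_WEIGHTS)
    for group, rates in BACKGROUND_RATES.items():
        members = responders if group == RESPONDER else nonresponders
        for gene, rate in sorted(rates.items()):
            region = _GENE_REGION[gene]
            counts = rng_var.poisson(rate, len(members))
            for pi, (pid, k) in enumerate(zip(members, counts)):
                for j in range(k):
                    cls = rng_var.choice(bg_classes, p=bg_weights)
                    vtype = _classification_to_type(cls)
                    # patient-unique position: background variants are never shared
                    offset = 20_000 + patient_ids.index(pid) * 500 + j * 7
                    if vtype == "SNP":
                        ref, alt = rng_var.choice(snv_classes, p=snv_weights).split(">")
                    elif vtype == "DEL":
                        ref, alt = "CA", "C"
                    else:
                        ref, alt = "C", "CT"
                    variants.append(
                        VariantRecord(
                            patient_id=pid, gene=gene, chrom=region.chrom,
                            pos=region.start + offset, ref=ref, alt=alt,
                            variant_classification=cls, variant_type=vtype,
                        )
                    )

    # burden gene (CCT3 by default): patient-unique variants whose count in
    # non-responders drives the planted burden-delta association
    k_nb = (config.assoc_burden_mean**2) / max(
        config.assoc_burden_sd**2 - config.assoc_burden_mean, 1e-9
    )
    p_nb = k_nb / (k_nb + config.assoc_burden_mean)
    burden = rng_delta.negative_binomial(k_nb, p_nb, n)
    assoc_region = _GENE_REGION[config.assoc_gene]
    for pi, pid in enumerate(patient_ids):
        for j in range(int(burden[pi])):
            variants.append(
                VariantRecord(
                    patient_id=pid, gene=config.assoc_gene,
                    chrom=assoc_region.chrom,
                    pos=assoc_region.start + 100 + pi * 500 + j * 3,
                    ref="C", alt="T",
                    variant_classification="missense", variant_type="SNP",
                )
            )

    # --- biological-age deltas and beta matrices ------------------------
    delta = np.empty(n)
    delta[:n_r] = rng_delta.normal(
        config.age_delta_responder_mean, config.age_delta_responder_sd, n_r
    )
    delta[n_r:] = (
        config.age_delta_nonresponder_mean
        + config.assoc_slope * (burden[n_r:] - config.assoc_burden_mean)
        + rng_delta.normal(0.0, config.assoc_noise_sd, n_n)
    )
    bioage_before = np.clip(
        ages + rng_delta.normal(0.0, config.bioage_baseline_sd, n), 1.0, None
    )
    bioage_after = np.clip(bioage_before + delta, 1.0, None)

    methylome = random_methylome(
        config.clock_cpg_count, config.clock_signal_count,
        seed=rng_meth, adult_age=config.adult_age,
    )
    beta_seeds = rng_beta.spawn(4)
    train_ages = pd.Series(
        np.random.default_rng(beta_seeds[3]).uniform(20.0, 90.0, config.clock_train_n),
        index=[f"REF{i + 1:03d}" for i in range(config.clock_train_n)],
    )
    beta_train = generate_beta_matrix(
        train_ages.to_numpy(), methylome, config.noise_sd, seed=beta_seeds[0],
        sample_ids=list(train_ages.index), n_noise_cpgs=config.noise_cpg_count,
    )
    beta_before = generate_beta_matrix(
        bioage_before, methylome, config.noise_sd, seed=beta_seeds[1],
        sample_ids=patient_ids, n_noise_cpgs=config.noise_cpg_count,
    )
    beta_after = generate_beta_matrix(
        bioage_after, methylome, config.noise_sd, seed=beta_seeds[2],
        sample_ids=patient_ids, n_noise_cpgs=config.noise_cpg_count,
    )

    truth = {
        "labels": dict(zip(patient_ids, group_truth)),
        "delta": dict(zip(patient_ids, delta)),
        "bioage_before": dict(zip(patient_ids, bioage_before)),
        "bioage_after": dict(zip(patient_ids, bioage_after)),
        "burden": dict(zip(patient_ids, (int(b) for b in burden))),
        "methylome": methylome,
    }
    return CohortDataset(
        cohort=cohort,
        line1=line1,
        beta_before=beta_before,
        beta_after=beta_after,
        beta_train=beta_train,
        train_ages=train_ages,
        whitelist=list(methylome.cpg_ids),
        variants=variants,
        annotation_db=annotation_db,
        panel=default_panel(),
        pathway_map=default_pathway_map(),
        truth=truth,
    )
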