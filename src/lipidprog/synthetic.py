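"""Synthetic multi-omics cohort generator with planted ground truth.

The generator emulates a ~100-patient liver-cancer cohort profiled by
shotgun lipidomics (~800 species across the full headgroup vocabulary,
~20% ether-linked), bulk gene expression, and right-censored overall
survival, with the statistical structure the analysis pipeline is built
to detect:

* two lipidome subtypes; subtype "A" samples carry a log10 shift
  (``ether_effect``) on every ether-linked species;
* skewed (log-normal) raw abundances with abundance-dependent (MNAR)
  missingness — low-abundance cells are preferentially missing, which is
  what justifies half-minimum imputation;
* a module of genes driven by each sample's mean ether-lipid level, the
  remaining genes independent noise;
* exponential survival with hazard ``baseline_hazard * exp(subtype_log_hr)``
  for subtype A, independent uniform censoring calibrated to a target
  censoring fraction, and administrative censoring at 2000 days.

Everything is deterministic given ``seed``; the emitted species names use
field shorthand (e.g. ``PC O-34:2``) so the nomenclature parser sits in
the tested path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import AbundanceMatrix, ClinicalTable
from .errors import ConfigError
from .nomenclature import ETHER_CLASSES

#: ~800 species, 160 (20%) ether-linked, mirroring a tissue shotgun run
DEFAULT_CLASS_COMPOSITION: dict[str, int] = {
    "PC": 85, "PE": 65, "TAG": 110, "DAG": 40, "SM": 50, "Cer": 40,
    "HexCer": 20, "CE": 30, "PI": 35, "PS": 30, "PG": 20, "PA": 20,
    "CL": 20, "LPC": 20, "LPE": 15, "LPA": 10, "LPG": 10, "LPI": 10,
    "LPS": 10,
    "PC O-": 75, "PE O-": 55, "LPC O-": 10, "LPE O-": 20,
}

# plausible total-carbon ranges per class family for name generation
_CARBON_RANGES = {
    "TAG": (42, 68), "DAG": (28, 44), "CL": (60, 80), "CE": (14, 24),
    "LPA": (14, 24), "LPC": (14, 24), "LPE": (14, 24), "LPG": (14, 24),
    "LPI": (14, 24), "LPS": (14, 24), "LPC O-": (14, 24), "LPE O-": (14, 24),
}
_DEFAULT_CARBON_RANGE = (28, 44)
_SPHINGO = {"Cer", "SM", "HexCer"}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; fully determines the cohort given ``seed``."""

    n_samples: int = 100
    n_species: int = 800
    class_composition: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COMPOSITION)
    )
    n_genes: int = 1000
    subtype_fraction: float = 0.5
    ether_effect: float = 1.0            # log10 shift on ether species in subtype A
    lipid_noise_sd: float = 0.25         # log10 units
    missing_logistic_params: tuple[float, float] = (-1.0, 4.0)  # (midpoint, slope)
    baseline_log10_range: tuple[float, float] = (-1.0, 2.0)
    n_module_genes: int = 50
    gene_noise_sd: float = 0.3
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    subtype_log_hr: float = float(np.log(2.5))
    censor_rate: float = 0.2
    max_follow_up_days: float = 2000.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_species < 1 or self.n_genes < 1:
            raise ConfigError("counts must be positive (n_samples >= 4)")
        if not 0 < self.subtype_fraction < 1:
            raise ConfigError("subtype_fraction must be in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.lipid_noise_sd <= 0 or self.gene_noise_sd <= 0:
            raise ConfigError("noise sds must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if self.n_module_genes > self.n_genes:
            raise ConfigError("n_module_genes cannot exceed n_genes")
        unknown = set(self.class_composition) - set(DEFAULT_CLASS_COMPOSITION)
        if unknown:
            raise ConfigError(f"unknown classes in composition: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    subtype: pd.Series                     # sample -> {A, B}
    planted_species: list[str]             # species shifted in subtype A (all ether)
    module_genes: list[str]
    true_log_hr: float


def _species_names(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    """Unique shorthand names honouring class_composition, scaled to n_species."""
    comp = cfg.class_composition
    total = sum(comp.values())
    # rescale composition to n_species, keeping every class non-empty
    counts = {c: max(1, round(k * cfg.n_species / total)) for c, k in comp.items()}
    while sum(counts.values()) != cfg.n_species:
        drift = 1 if sum(counts.values()) < cfg.n_species else -1
        cls = rng.choice([c for c in counts if counts[c] + drift >= 1])
        counts[cls] += drift
    names: list[str] = []
    for cls, k in counts.items():
        lo, hi = _CARBON_RANGES.get(cls, _DEFAULT_CARBON_RANGE)
        grid = [(c, d) for c in range(lo, hi + 1) for d in range(0, 9)]
        picks = rng.choice(len(grid), size=k, replace=False)
        suffix = ";2" if cls in _SPHINGO else ""
        sep = "" if cls.endswith("O-") else " "
        for idx in picks:
            c, d = grid[idx]
            names.append(f"{cls}{sep}{c}:{d}{suffix}")
    return names


def _calibrate_censor_horizon(hazards: np.ndarray, censor_rate: float) -> float:
    """Upper bound of Uniform(0, c) censoring giving the target censoring fraction.

    For exponential survival with rate lam and C ~ U(0, c):
    P(C < T) = (1 - exp(-lam c)) / (lam c), averaged over subjects.
    """
    def expected_censoring(c: float) -> float:
        lc = hazards * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-6, 1e9
    return float(brentq(lambda c: expected_censoring(c) - censor_rate, lo, hi, xtol=1e-6))


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame, ClinicalTable, GroundTruth]:
    """Generate (raw lipid matrix, gene matrix, clinical table, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    species = _species_names(cfg, rng)
    ether_mask = np.array([any(s.startswith(e) for e in ETHER_CLASSES) for s in species])

    n_a = int(round(cfg.subtype_fraction * cfg.n_samples))
    subtype = np.array(["A"] * n_a + ["B"] * (cfg.n_samples - n_a))
    subtype = rng.permutation(subtype)
    is_a = subtype == "A"

    lo, hi = cfg.baseline_log10_range
    baseline = rng.uniform(lo, hi, size=len(species))
    log_true = np.tile(baseline[:, None], (1, cfg.n_samples))
    log_true[np.ix_(ether_mask, is_a)] += cfg.ether_effect
    log_obs = log_true + rng.normal(0.0, cfg.lipid_noise_sd, size=log_true.shape)

    midpoint, slope = cfg.missing_logistic_params
    p_miss = 1.0 / (1.0 + np.exp(slope * (log_obs - midpoint)))
    missing = rng.uniform(size=log_obs.shape) < p_miss
    raw = np.power(10.0, log_obs)
    raw[missing] = np.nan

    lipids = AbundanceMatrix(
        pd.DataFrame(raw, index=species, columns=samples),
        scale="raw",
        sample_groups=pd.Series(subtype, index=samples),
    )

    # genes: module driven by per-sample mean ether log-abundance (log-scale units)
    ether_score = log_true[ether_mask].mean(axis=0)
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    module_idx = rng.choice(cfg.n_genes, size=cfg.n_module_genes, replace=False)
    expr = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    expr += rng.uniform(2.0, 8.0, size=(cfg.n_genes, 1))  # per-gene baseline
    expr[module_idx] = (
        ether_score[None, :]
        + rng.uniform(2.0, 8.0, size=(cfg.n_module_genes, 1))
        + rng.normal(0.0, cfg.gene_noise_sd, size=(cfg.n_module_genes, cfg.n_samples))
    )
    genes = pd.DataFrame(expr, index=gene_ids, columns=samples)

    # survival: exponential with subtype-dependent hazard
    hazards = cfg.baseline_hazard * np.exp(cfg.subtype_log_hr * is_a.astype(float))
    t_event = rng.exponential(1.0 / hazards)
    if cfg.censor_rate > 0:
        horizon = _calibrate_censor_horizon(hazards, cfg.censor_rate)
        t_cens = rng.uniform(0.0, horizon, size=cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    over = time > cfg.max_follow_up_days
    time[over] = cfg.max_follow_up_days
    event[over] = False
    time = np.maximum(time, 1e-3)  # keep times strictly positive

    clinical = ClinicalTable(
        pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample_id"))
    )
    truth = GroundTruth(
        subtype=pd.Series(subtype, index=samples, name="subtype"),
        planted_species=[s for s, m in zip(species, ether_mask) if m],
        module_genes=[gene_ids[i] for i in sorted(module_idx)],
        true_log_hr=cfg.subtype_log_hr,
    )
    return lipids, genes, clinical, truth


def simulate_survival(
    n: int,
    log_hr: float,
    baseline_hazard: float = 1.0 / 1000.0,
    censor_rate: float = 0.2,
    seed: int = 42,
    max_follow_up_days: float = float("inf"),
) -> tuple[pd.Series, ClinicalTable]:
    """Two-group exponential survival with calibrated uniform censoring.

    Returns (group indicator 0/1 per sample, clinical table); group 1
    (half the cohort) has hazard ``baseline_hazard * exp(log_hr)``.  Used
    for HR parameter-recovery checks without the lipidome overhead.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    x = np.zeros(n)
    x[rng.permutation(n)[: n // 2]] = 1.0
    hazards = baseline_hazard * np.exp(log_hr * x)
    t_event = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        horizon = _calibrate_censor_horizon(hazards, censor_rate)
        t_cens = rng.uniform(0.0, horizon, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    over = time > max_follow_up_days
    time[over] = max_follow_up_days
    event[over] = False
    clin = ClinicalTable(
        pd.DataFrame(
            {"time": np.maximum(time, 1e-3), "event": event},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return pd.Series(x, index=samples), clin


def write_fixture(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the generated cohort to disk in the pipeline's input formats.

    Emits ``lipids.tsv`` (wide species x samples, empty cell = missing),
    ``genes.tsv``, ``clinical.csv`` and ``ground_truth.json``; byte-stable
    for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lipids, genes, clinical, truth = generate_cohort(cfg)

    paths = {
        "lipids": outdir / "lipids.tsv",
        "genes": outdir / "genes.tsv",
        "clinical": outdir / "clinical.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    lipids.data.to_csv(paths["lipids"], sep="\t", float_format="%.6g",
                       index_label="species_id", na_rep="")
    genes.to_csv(paths["genes"], sep="\t", float_format="%.6g", index_label="gene_id")
    clin = clinical.table.copy()
    clin["event"] = clin["event"].astype(int)
    clin["group"] = truth.subtype
    clin.to_csv(paths["clinical"], float_format="%.6g", index_label="sample_id")
    payload = {
        "subtype": truth.subtype.to_dict(),
        "planted_species": truth.planted_species,
        "module_genes": truth.module_genes,
        "true_log_hr": truth.true_log_hr,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths
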