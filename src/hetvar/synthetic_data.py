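"""Synthetic pedigree + first-lactation record generator with known truth.

The generator emulates the statistical structure the analysis assumes: a
founder population of shared sires and dams, one record per recorded animal,
herd x year x season contemporary groups of variable size (some below the
three-record retention threshold), a bimodal distribution of
contemporary-group effects that makes LOW and HIGH phenotypic-SD classes
emerge from the standard preprocessing, and class-heterogeneous additive and
residual variances with a chosen cross-class genetic correlation.  Every
random quantity flows from a single seed, so a configuration reproduces its
files bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import UNKNOWN, Pedigree, inbreeding
from .preprocess import HIGH, LOW, RECORD_COLUMNS, PreparedDataset, prepare

__all__ = ["SimulationConfig", "TruthSet", "simulate_pedigree",
           "simulate_breeding_values", "simulate_records", "simulate",
           "apply_true_classes"]


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Defaults reproduce the scale of the motivating buffalo study: 2392
    records, 77 sires, about 160 contemporary groups over 10 herds x 4
    years x 4 seasons, age at calving 73.80 +/- 36.61 months, and true
    variance components at the study's posterior means with a cross-class
    genetic correlation of 0.61.  Contemporary-group effects are drawn from
    a two-component normal mixture whose components sit at the LOW/HIGH
    class mean yields, so that emergent class assignment matches the
    generating class for all but knife-edge groups.
    """

    n_sires: int = 77
    n_dams: int = 1196
    n_records: int = 2392
    n_herds: int = 10
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    season_probs: tuple[float, ...] = (0.30, 0.30, 0.20, 0.20)

    mean_yield: float = 2269.72          # kg, overall MP305 mean
    cg_shift_low: float = -198.18        # LOW component offset, kg
    cg_shift_high: float = 372.97        # HIGH component offset, kg
    cg_effect_sd: float = 110.0          # within-component SD, kg
    p_low_cg: float = 0.565              # fraction of LOW-class groups

    sigma2_a_low: float = 353.51
    sigma2_a_high: float = 1134.22
    sigma2_e_low: float = 1480.62
    sigma2_e_high: float = 2180.15
    rg: float = 0.61

    beta_htz: float = 50.0               # kg per unit heterozygosity
    beta_age: float = 1.5                # kg per month of age (centered)
    age_mean: float = 73.80
    age_sd: float = 36.61
    age_min: float = 20.0
    ll_mean: float = 270.0               # lactation length, days
    ll_sd: float = 40.0
    ll_min: float = 120.0
    ll_max: float = 365.0
    ll_slope: float = 5.47111            # true yield-on-length slope, kg/day

    class_assignment: str = "emergent"   # or "forced"
    seed: int = 0
    herd_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (-1.0 < self.rg < 1.0):
            raise ValueError("genetic correlation must lie in (-1, 1)")
        for name in ("sigma2_a_low", "sigma2_a_high",
                     "sigma2_e_low", "sigma2_e_high"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_records < 3:
            raise ValueError("need at least one full contemporary group")

    @property
    def G0(self) -> np.ndarray:
        cov = self.rg * np.sqrt(self.sigma2_a_low * self.sigma2_a_high)
        return np.array([[self.sigma2_a_low, cov], [cov, self.sigma2_a_high]])


@dataclass
class TruthSet:
    """Ground truth emitted next to the simulated files."""

    config: SimulationConfig
    breeding_values: pd.DataFrame        # animal, bv_low, bv_high
    cg_effects: pd.DataFrame             # cg_id, effect, true_class
    record_truth: pd.DataFrame           # animal, cg_id, true_class, signal
    variance_components: dict[str, float] = field(default_factory=dict)


def simulate_pedigree(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> Pedigree:
    """Founder sires/dams plus one row per recorded animal.

    Sires and dams are drawn uniformly for each recorded animal, which
    spreads every sire's offspring across herds and classes — the genetic
    links that make the cross-class correlation estimable.  Founders get
    Murrah fractions (mostly purebred, some crossbred) used later for the
    heterozygosity covariate.
    """
    rng = rng or np.random.default_rng(config.seed)
    sires = [f"S{i:03d}" for i in range(1, config.n_sires + 1)]
    dams = [f"D{i:04d}" for i in range(1, config.n_dams + 1)]
    offspring = [f"B{i:04d}" for i in range(1, config.n_records + 1)]
    entries = [(s, UNKNOWN, UNKNOWN) for s in sires]
    entries += [(d, UNKNOWN, UNKNOWN) for d in dams]
    sire_of = rng.choice(sires, size=config.n_records)
    dam_of = rng.choice(dams, size=config.n_records)
    entries += [(o, s, d) for o, s, d in zip(offspring, sire_of, dam_of)]
    frac = {}
    for s in sires:
        frac[s] = 1.0 if rng.random() < 0.85 else float(rng.uniform(0.25, 1.0))
    for d in dams:
        frac[d] = 1.0 if rng.random() < 0.60 else float(rng.uniform(0.0, 1.0))
    return Pedigree(entries=entries, breed_fraction=frac)


def simulate_breeding_values(ped: Pedigree, G0: np.ndarray,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Breeding-value pairs: founders ~ N(0, G0), offspring = parent average
    plus a Mendelian-sampling deviation with covariance
    ``(0.5 - 0.25*(F_s + F_d)) * G0``.
    """
    if np.any(np.linalg.eigvalsh(G0) < -1e-10):
        raise ValueError("G0 must be positive (semi)definite")
    sorted_ped, F = inbreeding(ped)
    idx = {a: i for i, a in enumerate(sorted_ped.animals)}
    n = len(sorted_ped)
    bv = np.zeros((n, 2))
    # G0 may be singular (e.g. the all-zero matrix); use an eigen square root
    w, V = np.linalg.eigh(G0)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    for i, (a, s, d) in enumerate(sorted_ped.entries):
        z = rng.standard_normal(2)
        if s == UNKNOWN and d == UNKNOWN:
            bv[i] = L @ z
            continue
        pa = np.zeros(2)
        fs = F[idx[s]] if s != UNKNOWN else -1.0
        fd = F[idx[d]] if d != UNKNOWN else -1.0
        if s != UNKNOWN:
            pa += 0.5 * bv[idx[s]]
        if d != UNKNOWN:
            pa += 0.5 * bv[idx[d]]
        ms_var = 0.5 - 0.25 * (fs + fd)
        bv[i] = pa + np.sqrt(ms_var) * (L @ z)
    return pd.DataFrame({
        "animal": sorted_ped.animals, "bv_low": bv[:, 0], "bv_high": bv[:, 1],
    })


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_records(ped: Pedigree, bvs: pd.DataFrame,
                     config: SimulationConfig,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, TruthSet]:
    """Phenotypes from the generating model.

    Each record's MP305 signal is overall mean + contemporary-group effect +
    heterozygosity and age covariate terms + the breeding-value component of
    its group's class; the residual is drawn with the class residual
    variance.  Total yield is then back-computed through the true
    yield-on-length slope so the preprocessing recovers MP305 exactly.
    """
    n = config.n_records
    animals = [a for a, s, d in ped.entries if s != UNKNOWN or d != UNKNOWN]
    if len(animals) != n:
        raise ValueError("pedigree does not match the configured record count")
    parent = {a: (s, d) for a, s, d in ped.entries}
    bv_map = bvs.set_index("animal")

    weights = config.herd_weights or tuple(range(1, config.n_herds + 1))
    w = np.asarray(weights, float)
    herds = rng.choice([f"H{i:02d}" for i in range(1, config.n_herds + 1)],
                       size=n, p=w / w.sum())
    years = rng.choice(config.years, size=n)
    season = rng.choice([1, 2, 3, 4], size=n, p=config.season_probs)
    month = np.array([int(rng.integers((s - 1) * 3 + 1, s * 3 + 1))
                      for s in season])
    age = _truncnorm(rng, config.age_mean, config.age_sd,
                     config.age_min, np.inf, n)
    ll = _truncnorm(rng, config.ll_mean, config.ll_sd,
                    config.ll_min, config.ll_max, n)

    cells = pd.DataFrame({"herd": herds, "year": years, "cs": season})
    cg_id = cells["herd"] + ":" + cells["year"].astype(str) + ":" + \
        cells["cs"].astype(str)
    unique_cg = sorted(cg_id.unique())
    # larger groups are more often LOW-class (the field pattern this mimics:
    # big average herds dominate the low-variability class), tilting the
    # record split toward LOW beyond the group-level fraction p_low_cg
    sizes = cg_id.value_counts().loc[unique_cg].to_numpy(float)
    p_low = np.clip(config.p_low_cg * (sizes / sizes.mean()) ** 0.75,
                    0.05, 0.95)
    is_low = rng.random(len(unique_cg)) < p_low
    shift = np.where(is_low, config.cg_shift_low, config.cg_shift_high)
    eff = shift + config.cg_effect_sd * rng.standard_normal(len(unique_cg))
    cg_table = pd.DataFrame({
        "cg_id": unique_cg, "effect": eff,
        "true_class": np.where(is_low, LOW, HIGH),
    }).set_index("cg_id")

    rec_class = cg_table.loc[cg_id, "true_class"].to_numpy()
    rec_effect = cg_table.loc[cg_id, "effect"].to_numpy()
    bv_low = bv_map.loc[animals, "bv_low"].to_numpy()
    bv_high = bv_map.loc[animals, "bv_high"].to_numpy()
    a_term = np.where(rec_class == LOW, bv_low, bv_high)
    e_sd = np.where(rec_class == LOW, np.sqrt(config.sigma2_e_low),
                    np.sqrt(config.sigma2_e_high))

    sire_mf = np.array([ped.breed_fraction.get(parent[a][0], 1.0)
                        for a in animals])
    dam_mf = np.array([ped.breed_fraction.get(parent[a][1], 1.0)
                       for a in animals])
    htz = sire_mf * (1 - dam_mf) + (1 - sire_mf) * dam_mf

    signal = (config.mean_yield + rec_effect + config.beta_htz * htz
              + config.beta_age * (age - config.age_mean) + a_term)
    mp305 = signal + e_sd * rng.standard_normal(n)
    tmp = mp305 - config.ll_slope * (305.0 - ll)

    records = pd.DataFrame({
        "animal": animals, "herd": herds, "year": years, "month": month,
        "age_months": age, "tmp_kg": tmp, "ll_days": ll,
        "sire_mf": sire_mf, "dam_mf": dam_mf,
    })[RECORD_COLUMNS]
    truth = TruthSet(
        config=config,
        breeding_values=bvs,
        cg_effects=cg_table.reset_index(),
        record_truth=pd.DataFrame({
            "animal": animals, "cg_id": cg_id.to_numpy(),
            "true_class": rec_class, "signal": signal,
        }),
        variance_components={
            "sigma2_a_low": config.sigma2_a_low,
            "sigma2_a_high": config.sigma2_a_high,
            "sigma_a_lh": float(config.G0[0, 1]),
            "sigma2_e_low": config.sigma2_e_low,
            "sigma2_e_high": config.sigma2_e_high,
        },
    )
    return records, truth


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, Pedigree, TruthSet]:
    """Pedigree + records + truth from one seed."""
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    bvs = simulate_breeding_values(ped, config.G0, rng)
    records, truth = simulate_records(ped, bvs, config, rng)
    return records, ped, truth


def apply_true_classes(prep: PreparedDataset, truth: TruthSet) -> PreparedDataset:
    """Replace emergent SD-class labels with the generating classes.

    Used by recovery tests that need the two-trait structure free of the
    (small) label noise that emergent classification adds at class
    boundaries.
    """
    labels = truth.record_truth.set_index("animal")["true_class"]
    data = prep.data.copy()
    data["sd_class"] = data["animal"].map(labels)
    data.loc[~data["retained"], "sd_class"] = pd.NA
    return PreparedDataset(data=data, ll_slope=prep.ll_slope,
                           cg_means=prep.cg_means,
                           cg_means_standardized=prep.cg_means_standardized)
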