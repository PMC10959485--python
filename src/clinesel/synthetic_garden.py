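"""Synthetic common-garden trials with known genetic truth.

The generator reproduces the statistical structure of a multi-population
open-pollinated progeny trial of Scots pine:

* one focal population of 500 half-sib families with ~24 offspring in 6
  blocks, plus 5 latitudinal populations of 10 families with ~12 offspring;
* population trait means on linear latitudinal clines (budset timing,
  first-year height, latent frost injury, seed weight);
* zero-mean multivariate family effects with covariance ``G`` — the
  between-family component, i.e. 1/4 of the additive variance under the
  half-sib assumption (fathers are never simulated explicitly);
* shared greenhouse block effects and multivariate residuals ``E``;
* ordinal 0-4 frost-injury scores thresholded from the latent damage value;
* family fitness from a user-specified quadratic (Lande-Arnold) selection
  surface on SD-standardized family values, expressed both as per-seedling
  survival and as age-9 height with dead trees at height 0.

Every dataset is accompanied by a :class:`SimulationTruth` carrying the
realized family effects, the true heritabilities and genetic correlations,
and the true selection gradients, so each downstream estimator can be tested
for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clinesel.errors import ConfigError
from clinesel.trial_data import TrialTable

TRAITS = ("BST", "FYH", "FFI", "SW")

# survival-census nesting: alive_2010/2011 probabilities as multiples of the
# final-census probability, calibrated to the focal population's printed
# survival trajectory (93% / 71% / 64%).
_CENSUS_RATIOS = (93.0 / 64.0, 71.0 / 64.0)


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    latitude: float
    n_families: int
    n_offspring: int
    n_blocks: int = 6


@dataclass(frozen=True)
class FitnessSpec:
    """Quadratic selection surface on SD-standardized family values.

    ``w = alpha + beta'f + sum_i (1/2) gamma_ii f_i^2 + sum_{i<k} gamma_ik f_i f_k + eps``

    ``gamma`` is the full-convention symmetric matrix (diagonal gamma_ii,
    off-diagonal gamma_ik).  ``survival_scale`` maps the surface value to a
    per-seedling survival probability before random mortality thinning;
    ``height_scale`` is the mean age-9 height (m) of survivors.
    """

    alpha: float = 1.0
    beta: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    gamma: tuple[tuple[float, ...], ...] = tuple(tuple(0.0 for _ in TRAITS) for _ in TRAITS)
    # real family-level fitness variation beyond the trait surface (site
    # micro-environment, maternal and unmeasured genetic effects): 15% CV,
    # large relative to the surface terms, as in field trials where most
    # family fitness variance is unexplained by the measured seedling traits
    noise_sd: float = 0.15
    random_mortality_rate: float = 0.25
    survival_scale: float = 0.85
    height_scale: float = 2.46
    height_sd: float = 0.55


@dataclass
class SimulationConfig:
    """Full generative description of a common-garden trial.

    Defaults (see :func:`default_config`) are the study conditions: clinal
    intercepts/slopes fitted to the published population means, within-focal
    variance components on the published scale, and the published
    family-level selection gradients as the fitness surface.
    """

    seed: int
    populations: tuple[PopulationSpec, ...]
    cline_intercepts: dict[str, float]
    cline_slopes: dict[str, float]
    G: np.ndarray                      # 4x4 between-family covariance (V_A / 4)
    E: np.ndarray                      # 4x4 residual covariance
    block_sd: dict[str, float]
    ffi_thresholds: tuple[float, float, float, float]
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    sw_effect: float = 0.0             # linear SW (standardized) effect on early survival
    shared_residuals: bool = True      # False: per-trait independent residuals
    no_budset_cutoff: float | None = None  # BST beyond this -> no terminal bud
    trial_year: int = 2008

    def validate(self) -> None:
        for name, m in (("G", self.G), ("E", self.E)):
            m = np.asarray(m, dtype=float)
            if m.shape != (4, 4) or not np.allclose(m, m.T, atol=1e-12):
                raise ConfigError(f"{name} must be a symmetric 4x4 matrix")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ConfigError(f"{name} is not positive semi-definite")
        t = np.asarray(self.ffi_thresholds, dtype=float)
        if len(t) != 4 or not np.all(np.diff(t) > 0):
            raise ConfigError("ffi_thresholds must be 4 strictly increasing cut points")
        if not (0.0 <= self.fitness.random_mortality_rate < 1.0):
            raise ConfigError("random_mortality_rate must lie in [0, 1)")
        n_blocks = {p.n_blocks for p in self.populations}
        if len(n_blocks) != 1:
            raise ConfigError("all populations must share the greenhouse blocks")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated trial."""

    family_effects: pd.DataFrame       # family_id, population + one column per trait
    block_effects: pd.DataFrame        # block x trait
    h2_true: dict[str, float]
    genetic_correlation: pd.DataFrame  # correlation of G
    beta_true: np.ndarray              # on the standardized family scale
    gamma_true: np.ndarray             # full convention
    expected_fitness: pd.Series        # per family, before noise/flooring
    floored_fitness_count: int = 0


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults.

    Cline intercepts/slopes are least-squares fits of published population
    means against latitude; G and E diagonals put the focal population's
    phenotypic variance and h2 on the published scale (BST V_P 83.6 with
    h2 0.48, FYH 250.3 / 0.57, latent FFI 0.83 / 0.33); G correlations are
    the published within-focal genetic correlations.  Frost-injury cut
    points are calibrated so the focal score mean is ~1.9.  The fitness
    surface defaults to the published height-inclusive-of-dead family
    gradients.
    """
    pops = (
        PopulationSpec("PUN", 61.75, 500, 24, 6),
        PopulationSpec("FINn", 67.19, 10, 12, 6),
        PopulationSpec("FINc", 63.75, 10, 12, 6),
        PopulationSpec("FINs", 60.87, 10, 12, 6),
        PopulationSpec("SWE", 56.47, 10, 12, 6),
        PopulationSpec("POL", 50.68, 10, 12, 6),
    )
    sf = np.array([10.1, 35.375, 0.0675, 0.0225])     # sigma2_family per trait
    se = np.array([73.5, 214.925, 0.7625, 1e-6])      # sigma2_residual (SW is family-level)
    corr = np.array([
        [1.00, 0.14, 0.19, 0.05],
        [0.14, 1.00, 0.35, 0.05],
        [0.19, 0.35, 1.00, 0.05],
        [0.05, 0.05, 0.05, 1.00],
    ])
    G = corr * np.sqrt(np.outer(sf, sf))
    E = np.diag(se)
    # BST and FYH are scored on the same seedlings, so they share residual
    # variation; 0.24 residual correlation puts the phenotypic BST-FYH
    # correlation at ~0.23 given G.  FFI comes from a separate sowing and
    # SW is family-level, so their residuals stay independent.
    E[0, 1] = E[1, 0] = 0.24 * np.sqrt(se[0] * se[1])
    # latent FFI cline puts the focal mean at 1.90; cut points are
    # mean + sd * (-1.45, -0.37, 0.58, 1.58) with sd = sqrt(0.83)
    mu_ffi = 14.37 - 0.202 * 61.75
    sd_ffi = np.sqrt(0.83)
    thresholds = tuple(mu_ffi + sd_ffi * c for c in (-1.45, -0.37, 0.58, 1.58))
    from clinesel.datasets import published_selection_gradients
    pub = published_selection_gradients("height-including-dead")
    fitness = FitnessSpec(alpha=1.0, beta=tuple(pub["beta"]),
                          gamma=tuple(map(tuple, pub["gamma_full"])))
    return SimulationConfig(
        seed=seed,
        populations=pops,
        cline_intercepts={"BST": 204.07, "FYH": 191.77, "FFI": 14.37, "SW": 2.126},
        cline_slopes={"BST": -1.666, "FYH": -2.314, "FFI": -0.202, "SW": -0.015},
        G=G,
        E=E,
        block_sd={"BST": 1.5, "FYH": 4.0, "FFI": 0.10, "SW": 0.0},
        ffi_thresholds=thresholds,
    )


def ordinalize_ffi(latent: np.ndarray, thresholds) -> np.ndarray:
    """Map latent frost damage to 0-4 scores.

    The score is the number of cut points strictly below the latent value,
    hence monotone non-decreasing in it.
    """
    t = np.asarray(thresholds, dtype=float)
    if len(t) != 4 or not np.all(np.diff(t) > 0):
        raise ConfigError("thresholds must be 4 strictly increasing values")
    return np.searchsorted(t, np.asarray(latent, dtype=float), side="left")


def quadratic_surface(f: np.ndarray, alpha: float, beta: np.ndarray,
                      gamma: np.ndarray) -> np.ndarray:
    """Expected fitness ``alpha + beta'f + f' (Gamma_halved) f`` per row of f.

    ``gamma`` uses the full convention; the quadratic form applies the 1/2
    on the diagonal, i.e. sum_i (1/2) gamma_ii f_i^2 + sum_{i<k} gamma_ik f_i f_k.
    """
    f = np.asarray(f, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    gh = gamma / 2.0
    return alpha + f @ np.asarray(beta, float) + np.einsum("ni,ij,nj->n", f, gh, f)


def simulate_fitness(family_traits: pd.DataFrame, spec: FitnessSpec, seed: int,
                     n_per_family: int | np.ndarray = 24,
                     ) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Family fitness and per-seedling survival from a quadratic surface.

    Parameters
    ----------
    family_traits : SD-standardized family values, one row per family,
        columns in trait order (BST, FYH, FFI, SW).
    n_per_family : seedlings per family for the survival draw.

    Returns
    -------
    W : per-family absolute fitness (surface value plus noise, floored at 0).
    survival : long DataFrame (family_id, seedling, alive) of Bernoulli
        survival with family probability
        ``survival_scale * (1 - random_mortality_rate) * W``, clipped to [0, 1].
    info : dict with the floored-fitness count and expected surface values.
    """
    rng = np.random.default_rng(seed)
    f = family_traits.to_numpy(dtype=float)
    expected = quadratic_surface(f, spec.alpha, np.asarray(spec.beta, float),
                                 np.asarray(spec.gamma, float))
    W = expected + rng.normal(0.0, spec.noise_sd, size=len(expected))
    floored = int((W < 0).sum())
    W = np.maximum(W, 0.0)
    p = np.clip(spec.survival_scale * (1.0 - spec.random_mortality_rate) * W, 0.0, 1.0)
    n = np.broadcast_to(np.asarray(n_per_family), (len(W),))
    fam_ids = np.repeat(family_traits.index.to_numpy(), n)
    probs = np.repeat(p, n)
    alive = (rng.random(len(probs)) < probs).astype(int)
    survival = pd.DataFrame({"family_id": fam_ids, "alive": alive})
    W = pd.Series(W, index=family_traits.index, name="fitness")
    info = {"floored": floored,
            "expected": pd.Series(expected, index=family_traits.index)}
    return W, survival, info


def _draw_mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Sample MVN(0, cov) robustly for PSD (possibly singular) cov."""
    w, v = np.linalg.eigh(np.asarray(cov, dtype=float))
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal((size, len(w)))
    return z * np.sqrt(w) @ v.T


def simulate_common_garden(config: SimulationConfig) -> tuple[TrialTable, SimulationTruth]:
    """Generate a full trial table plus its truth record.

    Deterministic given ``config.seed``.  Each seedling's trait value is
    clinal population mean + family effect + block effect + residual; frost
    injury is ordinalized from its latent value; survival and age-9 heights
    follow the fitness surface evaluated on the focal-population-standardized
    family values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_blocks = config.populations[0].n_blocks
    blocks = [f"B{i+1}" for i in range(n_blocks)]
    block_eff = pd.DataFrame(
        {t: rng.normal(0.0, config.block_sd.get(t, 0.0), size=n_blocks) for t in TRAITS},
        index=blocks,
    )

    fam_rows, rec_frames = [], []
    for pop in config.populations:
        mu = np.array([config.cline_intercepts[t] + config.cline_slopes[t] * pop.latitude
                       for t in TRAITS])
        fam_eff = _draw_mvn(rng, config.G, pop.n_families)
        fam_ids = [f"{pop.label}_F{j+1:04d}" for j in range(pop.n_families)]
        for j, fid in enumerate(fam_ids):
            fam_rows.append({"family_id": fid, "population": pop.label,
                             "latitude": pop.latitude,
                             **{t: fam_eff[j, i] for i, t in enumerate(TRAITS)}})
        per_block = max(pop.n_offspring // n_blocks, 1)
        n_seedlings = per_block * n_blocks
        if config.shared_residuals:
            resid = _draw_mvn(rng, config.E, pop.n_families * n_seedlings)
        else:
            sds = np.sqrt(np.diag(np.asarray(config.E, float)))
            resid = rng.standard_normal((pop.n_families * n_seedlings, 4)) * sds
        rows = {
            "family_id": np.repeat(fam_ids, n_seedlings),
            "block": np.tile(np.repeat(blocks, per_block), pop.n_families),
        }
        fam_part = np.repeat(fam_eff, n_seedlings, axis=0)
        blk_part = block_eff.loc[rows["block"]].to_numpy()
        values = mu + fam_part + blk_part + resid
        df = pd.DataFrame(rows)
        df["population"] = pop.label
        for i, t in enumerate(TRAITS):
            df[t] = values[:, i]
        rec_frames.append(df)

    truth_fam = pd.DataFrame(fam_rows)
    rec = pd.concat(rec_frames, ignore_index=True)

    # focal-population subpopulations mirror the two collection sites
    focal = config.populations[0].label
    focal_fams = truth_fam.loc[truth_fam["population"] == focal, "family_id"]
    n_focal = len(focal_fams)
    sub = np.where(np.arange(n_focal) < int(round(n_focal * 0.76)),
                   "Ranta-Halola", "Makra")
    submap = dict(zip(focal_fams, sub))
    rec["subpopulation"] = rec["family_id"].map(submap)

    rec["bst_days"] = np.maximum(rec["BST"], 1.0)
    rec["no_budset"] = False
    if config.no_budset_cutoff is not None:
        late = rec["bst_days"] > config.no_budset_cutoff
        rec.loc[late, "no_budset"] = True
        rec.loc[late, "bst_days"] = np.nan
    rec["fyh_mm"] = np.maximum(rec["FYH"], 0.0)
    rec["ffi_score"] = ordinalize_ffi(rec["FFI"].to_numpy(), config.ffi_thresholds)

    # family seed weight: cline + family effect, family-level (no residual)
    meta = truth_fam[["family_id", "population", "latitude"]].copy()
    mu_sw = config.cline_intercepts["SW"] + config.cline_slopes["SW"] * meta["latitude"]
    meta["seed_weight"] = np.maximum(mu_sw + truth_fam["SW"].to_numpy(), 1e-3)
    meta["longitude"] = np.nan
    meta["mother_age_years"] = pd.NA

    # fitness from the surface on focal-standardized family genetic values
    fam_values = truth_fam.set_index("family_id")[list(TRAITS)].copy()
    fam_values["SW"] = meta.set_index("family_id")["seed_weight"]
    focal_vals = fam_values.loc[truth_fam["population"].to_numpy() == focal]
    sds = focal_vals.std(ddof=1)
    center = focal_vals.mean()
    f_std = (fam_values - center) / sds
    spec = config.fitness
    fit_seed = int(rng.integers(0, 2**31 - 1))
    counts = rec.groupby("family_id", sort=False).size()
    counts = counts.loc[fam_values.index]
    W, survival, info = simulate_fitness(f_std, spec, fit_seed,
                                         n_per_family=counts.to_numpy())
    if config.sw_effect:
        # optional maternal seed-weight boost to early survival
        boost = np.clip(config.sw_effect * f_std["SW"], -0.5, 0.5)
        p_adj = np.clip(
            (spec.survival_scale * (1 - spec.random_mortality_rate) * W) * (1 + boost),
            0, 1)
        probs = np.repeat(p_adj.to_numpy(), counts.to_numpy())
        alive = (np.random.default_rng(fit_seed + 1).random(len(probs)) < probs)
        survival["alive"] = alive.astype(int)

    order = rec["family_id"].to_numpy()
    # survival rows are family-contiguous in the same family order as rec
    assert np.array_equal(survival["family_id"].to_numpy(), order)
    a17 = survival["alive"].to_numpy()
    # earlier censuses nest the final one: a dead-by-2017 seedling was alive
    # at an earlier census with the conditional probability that matches the
    # target marginals p10 >= p11 >= p17
    p17_fam = np.clip(spec.survival_scale * (1 - spec.random_mortality_rate)
                      * W.loc[fam_values.index].to_numpy(), 0, 1)
    p17_rec = rec["family_id"].map(
        pd.Series(p17_fam, index=fam_values.index)).to_numpy(float)
    p11 = np.clip(p17_rec * _CENSUS_RATIOS[1], p17_rec, 1)
    p10 = np.clip(p17_rec * _CENSUS_RATIOS[0], p11, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q11 = np.where(p17_rec < 1, (p11 - p17_rec) / (1 - p17_rec), 0.0)
    a11 = np.maximum(a17, (rng.random(len(order)) < q11).astype(int))
    with np.errstate(divide="ignore", invalid="ignore"):
        q10 = np.where(p11 < 1, (p10 - p11) / (1 - p11), 0.0)
    a10 = np.maximum(a11, (rng.random(len(order)) < q10).astype(int))
    rec["alive_2017"] = a17
    rec["alive_2011"] = a11
    rec["alive_2010"] = a10
    h = rng.normal(spec.height_scale, spec.height_sd, size=len(rec))
    rec["height9_m"] = np.where(rec["alive_2017"] == 1, np.maximum(h, 0.05), 0.0)

    rec["seedling_id"] = [f"S{i+1:06d}" for i in range(len(rec))]
    rec["trial_year"] = config.trial_year
    rec["greenhouse_dead"] = False
    rec["unhealthy"] = False
    rec["unidentified"] = False
    rec["excluded"] = False
    rec["exclusion_reason"] = ""
    cols = ["seedling_id", "family_id", "population", "subpopulation", "block",
            "trial_year", "bst_days", "no_budset", "fyh_mm", "ffi_score",
            "alive_2010", "alive_2011", "alive_2017", "height9_m",
            "greenhouse_dead", "unhealthy", "unidentified",
            "excluded", "exclusion_reason"]
    records = rec[cols].copy()
    records["ffi_score"] = records["ffi_score"].astype("Int64")
    for c in ("alive_2010", "alive_2011", "alive_2017", "trial_year"):
        records[c] = records[c].astype("Int64")
    for c in ("seedling_id", "family_id", "population", "subpopulation",
              "block", "exclusion_reason"):
        records[c] = records[c].astype("string")
    for c in ("no_budset", "greenhouse_dead", "unhealthy", "unidentified"):
        records[c] = records[c].astype("boolean")
    for c in ("bst_days", "fyh_mm", "height9_m"):
        records[c] = records[c].astype("Float64")

    meta_out = meta[["family_id", "population", "latitude", "longitude",
                     "mother_age_years", "seed_weight"]].copy()
    for c in ("family_id", "population"):
        meta_out[c] = meta_out[c].astype("string")
    for c in ("latitude", "longitude", "seed_weight"):
        meta_out[c] = meta_out[c].astype("Float64")
    meta_out["mother_age_years"] = meta_out["mother_age_years"].astype("Int64")

    table = TrialTable(records=records, meta=meta_out,
                       provenance=f"synthetic seed={config.seed}")

    Gd, Ed = np.diag(config.G), np.diag(np.asarray(config.E, float))
    h2_true = {t: (4.0 * Gd[i] / (Gd[i] + Ed[i]) if Gd[i] + Ed[i] > 0 else 0.0)
               for i, t in enumerate(TRAITS)}
    d = np.sqrt(np.clip(Gd, 1e-300, None))
    gcorr = pd.DataFrame(config.G / np.outer(d, d), index=TRAITS, columns=TRAITS)
    truth = SimulationTruth(
        family_effects=truth_fam,
        block_effects=block_eff,
        h2_true=h2_true,
        genetic_correlation=gcorr,
        beta_true=np.asarray(spec.beta, float),
        gamma_true=np.asarray(spec.gamma, float),
        expected_fitness=info["expected"],
        floored_fitness_count=info["floored"],
    )
    return table, truth
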