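"""End-to-end orchestration: validate -> fit -> correlate -> selection -> report.

``run_pipeline`` drives the full family-level analysis on either a simulated
or a loaded trial and writes tidy CSV/JSON artifacts plus a plain-text
report.  Outputs are deterministic given the configuration and seed; every
artifact directory carries the package version, the seed, and a hash of the
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clinesel.errors import ClineselError, DataError
from clinesel import trial_data
from clinesel.trial_data import (TrialTable, ExclusionRules, apply_exclusions,
                                 family_survival_proportions, read_trial_table)
from clinesel.synthetic_garden import SimulationConfig, default_config, simulate_common_garden
from clinesel.quantgen_model import (fit_family_model, additive_variance,
                                     dickerson_se)
from clinesel.correlation_suite import (correlation_levels, pearson_with_ci,
                                        variance_inflation_factors,
                                        subpop_mean_test)
from clinesel.selection_surface import (standardize_traits, relative_fitness,
                                        linear_gradients, quadratic_gradients,
                                        mardia_test, full_canonical,
                                        significance_stars)

log = logging.getLogger(__name__)

SEEDLING_TRAITS = {"BST": "bst_days", "FYH": "fyh_mm", "FFI": "ffi_score"}


@dataclass
class RunConfig:
    out_dir: str | Path
    seed: int = 0
    input_dir: str | Path | None = None          # load instead of simulate
    sim_config: SimulationConfig | None = None   # defaults to study conditions
    focal: str = "PUN"
    fitness_definitions: tuple[str, ...] = ("height-including-dead",
                                            "survival-proportion")
    gamma_convention: str = "halved"
    exclusion_rules: ExclusionRules = field(default_factory=ExclusionRules)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ClineselError as exc:
                raise ClineselError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("fit")
def _heritability_stage(table: TrialTable, focal: str):
    rec = table.records
    focal_tab = TrialTable(rec.loc[rec["population"] == focal].copy(),
                           table.meta, table.provenance)
    rows, estimates = [], {}
    for trait, col in SEEDLING_TRAITS.items():
        vc, fam = fit_family_model(focal_tab, col, fixed=("block",))
        h2 = dickerson_se(vc)
        rows.append({
            "trait": trait, "sigma2_family": vc.sigma2_family,
            "sigma2_residual": vc.sigma2_residual, "VA": additive_variance(vc),
            "VP": vc.VP, "h2": h2.h2, "se": h2.se, "n_families": vc.n_families,
            "n_obs": vc.n_obs, "converged": vc.converged,
            "boundary": vc.boundary, "warning": h2.warning,
        })
        estimates[trait] = fam
    return pd.DataFrame(rows), estimates, focal_tab


@_stage("fit-latitudinal")
def _latitudinal_stage(table: TrialTable, focal: str):
    rec = table.records
    lat_tab = TrialTable(rec.loc[rec["population"] != focal].copy(),
                         table.meta, table.provenance)
    estimates = {}
    for trait, col in SEEDLING_TRAITS.items():
        try:
            _, fam = fit_family_model(lat_tab, col, fixed=("block", "population"))
        except DataError as exc:
            log.warning("latitudinal fit for %s skipped: %s", trait, exc)
            continue
        estimates[trait] = fam
    return estimates, lat_tab


def _estimate_frame(estimates: dict, meta: pd.DataFrame, scale: str) -> pd.DataFrame:
    cols = {}
    for trait, fam in estimates.items():
        cols[trait] = fam.scale(scale)
    df = pd.DataFrame(cols)
    pop = meta.set_index("family_id")["population"]
    df["population"] = pop.reindex(df.index).astype(str)
    return df.dropna()


@_stage("correlate")
def _correlation_stage(focal_est, lat_est, table: TrialTable, focal: str):
    out = []
    meta = table.meta
    frames = {}
    if focal_est:
        frames["within-focal"] = _estimate_frame(focal_est, meta, "deviation")
    if lat_est:
        frames["within-pooled"] = _estimate_frame(lat_est, meta, "centered")
        frames["between-familywise"] = _estimate_frame(lat_est, meta,
                                                       "population_inclusive")
        frames["between-popmeans"] = frames["between-familywise"]
    for mode, frame in frames.items():
        try:
            ests = correlation_levels(frame, mode, focal=focal)
        except DataError as exc:
            log.warning("correlation level %s skipped: %s", mode, exc)
            continue
        for (a, b), e in ests.items():
            out.append({"trait_i": a, "trait_j": b, "r": e.r, "ci_low": e.ci_low,
                        "ci_high": e.ci_high, "n": e.n, "p": e.p, "level": mode})
    # phenotypic, seedling level, pairwise-complete
    rec = table.active()
    rec = rec.loc[rec["population"] == focal]
    pairs = [("BST", "FYH"), ("BST", "FFI"), ("FYH", "FFI")]
    for a, b in pairs:
        ca, cb = SEEDLING_TRAITS[a], SEEDLING_TRAITS[b]
        both = rec[[ca, cb]].dropna()
        if len(both) < 4:
            continue
        e = pearson_with_ci(both[ca].astype(float), both[cb].astype(float),
                            level="phenotypic")
        out.append({"trait_i": a, "trait_j": b, "r": e.r, "ci_low": e.ci_low,
                    "ci_high": e.ci_high, "n": e.n, "p": e.p,
                    "level": "phenotypic"})
    return pd.DataFrame(out)


def _selection_traits(focal_est, table: TrialTable, focal: str) -> pd.DataFrame:
    df = pd.DataFrame({t: focal_est[t].scale("deviation") for t in focal_est})
    meta = table.meta.set_index("family_id")
    sw = meta.loc[meta["population"] == focal, "seed_weight"].astype(float)
    df["SW"] = sw.reindex(df.index)
    return df.dropna()


@_stage("selection")
def _selection_stage(focal_est, table: TrialTable, focal_tab: TrialTable,
                     focal: str, definitions, convention: str):
    traits_df = _selection_traits(focal_est, table, focal)
    # BLUP deviations are already near mean zero; centering also zero-means
    # seed weight so the quadratic model's beta* and the index-variable
    # ranges are anchored at the trait means
    stt = standardize_traits(traits_df, center=True)
    mardia = mardia_test(stt.values)
    results = {}
    for definition in definitions:
        if definition == "height-including-dead":
            rec = focal_tab.records.copy()
            h = rec["height9_m"].astype(float)
            h = h.where(rec["alive_2017"] != 0, 0.0)
            rec["height9_incl_dead"] = h.astype("Float64")
            tab = TrialTable(rec, focal_tab.meta)
            vc, fam = fit_family_model(tab, "height9_incl_dead", fixed=("block",))
            if vc.boundary:
                # zero family variance -> BLUPs carry no information; fall
                # back to raw family means so the analysis stays defined
                log.warning("fitness REML at the zero-variance boundary; "
                            "using raw family means as fitness estimates")
                W = (rec.groupby("family_id")["height9_incl_dead"]
                     .mean().astype(float))
            else:
                W = fam.scale("centered")
            W = W.clip(lower=0.0)
        elif definition == "survival-proportion":
            props = family_survival_proportions(focal_tab, "alive_2017")
            W = props.set_index("family_id")["proportion"]
        else:
            raise DataError(f"unknown fitness definition {definition!r}")
        fv = relative_fitness(W, definition)
        lg = linear_gradients(fv, stt)
        qg = quadratic_gradients(fv, stt)
        dec = full_canonical(fv, stt, convention)
        results[definition] = {"fitness": fv, "linear": lg, "quadratic": qg,
                               "canonical": dec}
    return results, mardia, stt


def _gradients_frame(lg, qg) -> pd.DataFrame:
    rows = []
    for t in lg.beta.index:
        rows.append({"term": t, "kind": "beta", "estimate": lg.beta[t],
                     "se": lg.se[t], "p": lg.p[t],
                     "stars": significance_stars(lg.p[t])})
    for t in qg.gamma_ii.index:
        key = f"{t}^2"
        rows.append({"term": f"{t}:{t}", "kind": "gamma", "estimate": qg.gamma_ii[t],
                     "se": qg.se[key], "p": qg.p[key],
                     "stars": significance_stars(qg.p[key])})
    for key, v in qg.gamma_off.items():
        rows.append({"term": key, "kind": "gamma", "estimate": v,
                     "se": qg.se[key], "p": qg.p[key],
                     "stars": significance_stars(qg.p[key])})
    return pd.DataFrame(rows)


def _canonical_frame(dec) -> pd.DataFrame:
    rows = []
    for ax in dec.lam.index:
        row = {"axis": ax}
        for t in dec.M.index:
            row[f"load_{t}"] = dec.M.loc[t, ax]
        row.update({"theta": dec.theta[ax], "lambda": dec.lam[ax],
                    "z_star": dec.z_star[ax] if dec.z_star is not None else np.nan,
                    "min": dec.index_ranges.loc[ax, "min"],
                    "max": dec.index_ranges.loc[ax, "max"],
                    "theta_p": dec.theta_p[ax], "lambda_p": dec.lambda_p[ax],
                    "theta_stars": significance_stars(dec.theta_p[ax]),
                    "lambda_stars": significance_stars(dec.lambda_p[ax])})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write artifacts under ``config.out_dir``.

    Returns a dict of in-memory stage outputs (also useful for testing).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    if config.input_dir is not None:
        table = read_trial_table(config.input_dir)
        truth = None
    else:
        sim = config.sim_config or default_config(config.seed)
        table, truth = simulate_common_garden(sim)

    excl = apply_exclusions(table, config.exclusion_rules)
    table = excl.table

    herit, focal_est, focal_tab = _heritability_stage(table, config.focal)
    if (herit["boundary"]).any():
        warnings.append("boundary variance component in at least one trait fit")
    if (herit["h2"] > 1).any():
        warnings.append("h2 > 1 for at least one trait")
    lat_est, _ = _latitudinal_stage(table, config.focal)
    corr = _correlation_stage(focal_est, lat_est, table, config.focal)

    # collinearity and subpopulation checks on the focal estimates
    traits_df = _selection_traits(focal_est, table, config.focal)
    vifs = variance_inflation_factors(traits_df)
    sub = table.meta.set_index("family_id")
    subpop = None
    focal_rec = focal_tab.records
    submap = (focal_rec.drop_duplicates("family_id")
              .set_index("family_id")["subpopulation"])
    labels = submap.reindex(traits_df.index).dropna()
    if labels.nunique() == 2 and "BST" in traits_df.columns:
        vals = traits_df.loc[labels.index, "BST"]
        t, dfree, p, means = subpop_mean_test(vals.to_numpy(), labels.to_numpy())
        subpop = {"t": t, "df": dfree, "p": p, "group_means": means}

    selection, mardia, stt = _selection_stage(
        focal_est, table, focal_tab, config.focal,
        config.fitness_definitions, config.gamma_convention)

    # ---- artifacts
    herit.to_csv(out_dir / "heritability.csv", index=False)
    corr.to_csv(out_dir / "correlations.csv", index=False)
    for trait, fam in focal_est.items():
        fam.values.to_csv(out_dir / f"family_estimates_{trait}.csv")
    gradients_frames, canonical_frames = {}, {}
    for definition, res in selection.items():
        tag = definition.replace("-", "_")
        gf = _gradients_frame(res["linear"], res["quadratic"])
        cf = _canonical_frame(res["canonical"])
        gf.to_csv(out_dir / f"gradients_{tag}.csv", index=False)
        cf.to_csv(out_dir / f"canonical_{tag}.csv", index=False)
        gradients_frames[definition] = gf
        canonical_frames[definition] = cf
    with open(out_dir / "mardia.json", "w") as fh:
        json.dump(dataclasses.asdict(mardia), fh, indent=1)
    meta_info = {
        "package": "clinesel", "version": __import__("clinesel").__version__,
        "seed": config.seed, "config_hash": config.config_hash(),
        "exclusion_counts": excl.counts, "warnings": warnings,
        "vif": vifs.round(6).to_dict(),
        "subpopulation_test": subpop,
        "gamma_convention": config.gamma_convention,
    }
    with open(out_dir / "run.json", "w") as fh:
        json.dump(meta_info, fh, indent=1, default=float)

    outputs = {
        "table": table, "truth": truth, "exclusions": excl.counts,
        "heritability": herit, "correlations": corr, "vif": vifs,
        "subpopulation_test": subpop, "mardia": mardia,
        "selection": selection, "gradients": gradients_frames,
        "canonical": canonical_frames, "warnings": warnings,
        "meta": meta_info,
    }
    (out_dir / "report.md").write_text(make_report(outputs))
    return outputs


def _fmt(x, nd=4):
    return "nan" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}g}"


def make_report(outputs: dict) -> str:
    """Assemble a human-readable summary of all available stages."""
    lines = ["# Common-garden analysis report", ""]
    meta = outputs.get("meta", {})
    if meta:
        lines += [f"seed: {meta.get('seed')}  config: {meta.get('config_hash')}", ""]
    if outputs.get("warnings"):
        lines += ["**Warnings:** " + "; ".join(outputs["warnings"]), ""]

    herit = outputs.get("heritability")
    if herit is not None:
        lines += ["## Heritability", "",
                  "| trait | VA | VP | h2 | SE |", "|---|---|---|---|---|"]
        for _, r in herit.iterrows():
            lines.append(f"| {r['trait']} | {_fmt(r['VA'])} | {_fmt(r['VP'])} "
                         f"| {r['h2']:.2f} | {_fmt(r['se'], 2)} |")
        lines.append("")
    else:
        lines += ["## Heritability", "", "_stage absent_", ""]

    corr = outputs.get("correlations")
    if corr is not None:
        lines += ["## Correlations", ""]
        for level, grp in corr.groupby("level"):
            lines.append(f"### {level}")
            for _, r in grp.iterrows():
                lines.append(f"- {r['trait_i']}-{r['trait_j']}: r = {r['r']:.2f} "
                             f"({r['ci_low']:.2f}; {r['ci_high']:.2f}), n = {r['n']}"
                             f"{significance_stars(r['p'])}")
            lines.append("")
    else:
        lines += ["## Correlations", "", "_stage absent_", ""]

    grads = outputs.get("gradients")
    if grads:
        lines += ["## Selection gradients", ""]
        for definition, gf in grads.items():
            lines.append(f"### fitness: {definition}")
            for _, r in gf.iterrows():
                lines.append(f"- {r['kind']} {r['term']}: {r['estimate']:.3e} "
                             f"(SE {r['se']:.2e}){r['stars']}")
            lines.append("")
    else:
        lines += ["## Selection gradients", "", "_stage absent_", ""]

    canon = outputs.get("canonical")
    if canon:
        lines += ["## Canonical analysis", ""]
        for definition, cf in canon.items():
            lines.append(f"### fitness: {definition}")
            for _, r in cf.iterrows():
                lines.append(f"- {r['axis']}: lambda = {r['lambda']:.3e}"
                             f"{r['lambda_stars']}, theta = {r['theta']:.3e}"
                             f"{r['theta_stars']}, z* = {_fmt(r['z_star'], 3)}, "
                             f"range [{r['min']:.2f}, {r['max']:.2f}]")
            lines.append("")
    else:
        lines += ["## Canonical analysis", "", "_stage absent_", ""]
    return "\n".join(lines)
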