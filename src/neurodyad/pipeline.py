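"""End-to-end orchestration: network -> similarity -> dyad table -> inference.

`analyze_study` runs the whole analysis in memory; `run_pipeline` wraps it
with file I/O (reading the formats in :mod:`neurodyad.io`, writing a
result bundle plus a run log of every seed consumed).
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ndio
from .classification import ClassifierConfig, cross_validated_predict, label_permutation_test
from .glm import (
    ConvergenceError,
    deviation_coded_estimates,
    fit_binary_logit,
    fit_ordered_logit,
    lr_test,
    odds_interpretation,
    per_roi_regressions,
)
from .network import NominationMatrix, build_graph, geodesic_distances, network_stats, restrict_distances
from .resampling import ks_group_vs_rest, network_permutation_test, wilcoxon_group_vs_rest
from .similarity import (
    RoiTimeSeriesSet,
    build_dyad_table,
    dyadic_roi_correlations,
    impute_missing,
    normalize_per_roi,
    weighted_composite,
)

__all__ = ["RunConfig", "analyze_study", "run_pipeline", "CONTROLS"]

CONTROLS = ["diff_gender", "diff_ethnicity", "diff_nationality", "age_diff",
            "diff_handedness"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """File-driven pipeline configuration (flags mirror these fields)."""

    nominations: str
    timeseries_dir: str
    demographics: str
    volumes: str | None
    output_dir: str
    tie_rule: str = "reciprocal"
    distance_cap: int = 4
    weighting: str = "volume"  # or "equal"
    seed: int = 0
    n_network_perms: int = 1000
    n_label_perms: int = 0  # label-permutation test off by default (costly)
    n_outer_folds: int = 8
    n_inner_folds: int = 8

    def validate(self) -> None:
        for name in ("nominations", "timeseries_dir", "demographics"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name} input not found: {getattr(self, name)}")
        if self.weighting == "volume":
            if self.volumes is None or not Path(self.volumes).exists():
                raise FileNotFoundError("volume weighting requested but no volumes file")
        elif self.weighting != "equal":
            raise ValueError("weighting must be 'volume' or 'equal'")


def analyze_study(
    nominations: NominationMatrix,
    timeseries: RoiTimeSeriesSet,
    demographics: pd.DataFrame,
    volumes: pd.DataFrame | None = None,
    tie_rule: str = "reciprocal",
    distance_cap: int = 4,
    seed: int = 0,
    n_network_perms: int = 1000,
    n_label_perms: int = 0,
    classifier_config: ClassifierConfig | None = None,
    run_classifier: bool = True,
) -> dict:
    """Run the full dyadic analysis and return a result bundle (dict).

    Social distances are computed on the full nomination network, then
    restricted to the scanned subjects (those with time series).  The
    bundle contains the network statistics, the dyad table, the ordered
    and binary regression results with two-way clustered inference, the
    LR test for the added value of neural similarity, the per-ROI FDR
    table, deviation-coded category contrasts, KS / rank-sum tests and
    the node-relabeling permutation test per category, and (optionally)
    the cross-validated classifier results.
    """
    stats_ = network_stats(nominations)
    graph = build_graph(nominations, tie_rule)
    dres = geodesic_distances(graph, cap=distance_cap)
    scanned = list(timeseries.subject_ids)
    sub = restrict_distances(dres, scanned)

    sim = dyadic_roi_correlations(timeseries)
    sim = impute_missing(sim)
    sim = normalize_per_roi(sim)
    sim = weighted_composite(sim, volumes)
    table = build_dyad_table(sim, sub.capped_category, demographics, scanned)

    # a control with no variation (e.g. a fully right-handed sample) cannot
    # be standardized or estimated; drop it rather than fail the run
    controls = [c for c in CONTROLS if table[c].nunique() > 1]
    dropped = sorted(set(CONTROLS) - set(controls))
    if dropped:
        warnings.warn(f"constant control(s) dropped: {dropped}", stacklevel=2)
    predictors = ["similarity", *controls]
    ordered_full = fit_ordered_logit(table, predictors)
    ordered_reduced = fit_ordered_logit(table, controls)
    chi2, df, p_lr = lr_test(ordered_full, ordered_reduced)
    # the friendship (binary) model can be quasi-separated when few friend
    # dyads vary on a control; report the diagnosis instead of failing the run
    try:
        binary_full = fit_binary_logit(table, predictors)
        binary_reduced = fit_binary_logit(table, controls)
        chi2_b, df_b, p_lr_b = lr_test(binary_full, binary_reduced)
        lr_binary = {"chi2": chi2_b, "df": df_b, "p": p_lr_b}
    except ConvergenceError as exc:
        warnings.warn(f"binary friendship model not estimable: {exc}", stacklevel=2)
        binary_full = binary_reduced = None
        lr_binary = None
    fdr = per_roi_regressions(table, controls)
    deviation = deviation_coded_estimates(table, controls)

    cats = np.sort(table["distance"].unique())
    group_tests = {
        int(k): {
            "ks": dataclasses.asdict(
                ks_group_vs_rest(table["similarity"], table["distance"], k)
            ),
            "wilcoxon": dataclasses.asdict(
                wilcoxon_group_vs_rest(table["similarity"], table["distance"], k)
            ),
        }
        for k in cats
    }

    pos = {s: i for i, s in enumerate(scanned)}
    pairs = np.column_stack(
        [table["subject_i"].map(pos).to_numpy(), table["subject_j"].map(pos).to_numpy()]
    )
    perm = network_permutation_test(
        table["similarity"].to_numpy(), pairs, table["distance"].to_numpy(),
        n_perm=n_network_perms, seed=seed,
    )

    classifier = None
    if run_classifier:
        cfg = classifier_config or ClassifierConfig(seed=seed, n_label_perms=max(n_label_perms, 1))
        zcols = [c for c in table.columns if c.startswith("z_")]
        features = table[zcols].to_numpy()
        labels = table["distance"].to_numpy()
        classifier = cross_validated_predict(features, labels, cfg)
        if n_label_perms > 0:
            classifier = label_permutation_test(features, labels, cfg, observed=classifier)

    return {
        "network_stats": dataclasses.asdict(stats_),
        "dyad_table": table,
        "similarity": sim,
        "distances": sub,
        "ordered_full": ordered_full,
        "ordered_reduced": ordered_reduced,
        "lr_test": {"chi2": chi2, "df": df, "p": p_lr},
        "binary_full": binary_full,
        "binary_reduced": binary_reduced,
        "lr_test_binary": lr_binary,
        "odds_percent_friendship": (
            odds_interpretation(binary_full.beta[0]) if binary_full else None
        ),
        "fdr_table": fdr,
        "deviation_coded": deviation,
        "group_tests": group_tests,
        "network_permutation": perm,
        "classifier": classifier,
    }


def _model_json(result) -> dict:
    return {
        "model": result.model,
        "predictors": list(result.predictor_names),
        "beta": result.beta,
        "se": result.se,
        "p": result.p,
        "tau": result.tau,
        "loglik": result.loglik,
        "n_dyads": result.n_obs,
        "cluster": result.cluster,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Read inputs, run :func:`analyze_study`, write the result bundle.

    Outputs (CSV/JSON) land in ``config.output_dir`` together with
    ``run_log.txt`` recording the configuration and every derived seed.
    A failing stage raises with the stage name; files already written are
    retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    nominations = ndio.read_nominations(config.nominations)
    timeseries = ndio.read_timeseries_dir(config.timeseries_dir)
    demographics = ndio.read_demographics(config.demographics)
    volumes = ndio.read_volumes(config.volumes) if config.weighting == "volume" else None

    cfg = ClassifierConfig(
        seed=config.seed,
        n_outer_folds=config.n_outer_folds,
        n_inner_folds=config.n_inner_folds,
        n_label_perms=max(config.n_label_perms, 1),
    )
    bundle = analyze_study(
        nominations, timeseries, demographics, volumes,
        tie_rule=config.tie_rule, distance_cap=config.distance_cap,
        seed=config.seed, n_network_perms=config.n_network_perms,
        n_label_perms=config.n_label_perms, classifier_config=cfg,
    )

    ndio.write_dyad_table(bundle["dyad_table"], out / "dyad_table.csv")
    ndio.write_json(bundle["network_stats"], out / "network_stats.json")
    ndio.write_json(_model_json(bundle["ordered_full"]), out / "model_ordered_full.json")
    ndio.write_json(_model_json(bundle["ordered_reduced"]), out / "model_ordered_reduced.json")
    if bundle["binary_full"] is not None:
        ndio.write_json(_model_json(bundle["binary_full"]), out / "model_binary_full.json")
    ndio.write_json(bundle["lr_test"], out / "lr_test.json")
    bundle["fdr_table"].to_csv(out / "per_roi_fdr.csv", index=False)
    bundle["deviation_coded"].to_csv(out / "deviation_coded.csv", index=False)
    ndio.write_json(bundle["group_tests"], out / "group_tests.json")
    perm = bundle["network_permutation"]
    ndio.write_json(
        {"categories": perm.categories, "observed": perm.observed, "p": perm.p,
         "n_perm": perm.n_perm, "seed": perm.seed},
        out / "network_permutation.json",
    )
    pd.DataFrame(
        perm.null_distribution, columns=[f"distance_{c}" for c in perm.categories]
    ).to_csv(out / "network_permutation_null.csv", index=False)
    clf = bundle["classifier"]
    if clf is not None:
        pd.DataFrame(
            clf.confusion,
            index=[f"true_{c}" for c in clf.categories],
            columns=[f"pred_{c}" for c in clf.categories],
        ).to_csv(out / "confusion_matrix.csv")
        ndio.write_json(
            {"overall_accuracy": clf.overall_accuracy,
             "fold_mean_accuracy": clf.fold_mean_accuracy,
             "per_fold_accuracy": clf.per_fold_accuracy,
             "best_c_per_fold": clf.best_c_per_fold,
             "p": clf.p},
            out / "classifier.json",
        )
        if clf.permutation_null is not None:
            pd.DataFrame({"null_accuracy": clf.permutation_null}).to_csv(
                out / "classifier_null.csv", index=False
            )

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"run at {datetime.datetime.now().isoformat()}\n")
        fh.write(f"config: {dataclasses.asdict(config)}\n")
        fh.write(f"master seed: {config.seed}\n")
        fh.write(f"network permutation seed: {config.seed}\n")
        fh.write(f"classifier seeds derived from master via SeedSequence([seed, path])\n")
    return bundle
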