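"""Dyadic inter-subject similarity: per-ROI time-series correlations and the
volume-weighted composite.

For every unordered pair of scanned subjects (a *dyad*) and every ROI, the
similarity is the Pearson correlation between the two subjects' mean
response time series for that ROI, computed on the concatenated series.
Entries where either subject lacks the ROI are imputed with the ROI's mean
correlation over the observed dyads, each ROI's similarity vector is then
z-scored across dyads, and the composite similarity of a dyad is the
ROI-volume-weighted mean of its z-scores.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeriesSet",
    "SimilarityMatrix",
    "dyadic_roi_correlations",
    "impute_missing",
    "normalize_per_roi",
    "weighted_composite",
    "build_dyad_table",
    "dyad_pairs",
]


@dataclasses.dataclass(frozen=True)
class RoiTimeSeriesSet:
    """Per-subject ROI-mean response time series.

    ``series`` is [N_subjects x R x T]; ``present_mask`` marks which
    (subject, ROI) series exist (coverage loss makes some ROIs unusable
    for some subjects).  All subjects share the same T (concatenated runs).
    """

    series: np.ndarray
    present_mask: np.ndarray
    roi_names: tuple[str, ...]
    subject_ids: tuple[str, ...]
    volumes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.series, dtype=float)
        n, r, t = s.shape
        if len(self.subject_ids) != n or len(self.roi_names) != r:
            raise ValueError("subject_ids/roi_names do not match series shape")
        mask = np.asarray(self.present_mask, dtype=bool)
        if mask.shape != (n, r):
            raise ValueError("present_mask must be [N x R]")
        object.__setattr__(self, "series", s)
        object.__setattr__(self, "present_mask", mask)
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.series.shape[0]

    @property
    def n_rois(self) -> int:
        return self.series.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[2]


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    """Dyad x ROI similarity at its successive processing stages.

    ``raw`` holds Pearson r with NaN for unobserved entries; ``z`` the
    per-ROI z-scores (populated by :func:`normalize_per_roi`);
    ``composite`` the weighted row mean of ``z``.  ``dyad_index`` lists
    the (i, j) subject-id pairs, i before j in subject order.
    """

    raw: np.ndarray
    dyad_index: tuple[tuple[str, str], ...]
    roi_names: tuple[str, ...]
    imputed_flags: np.ndarray | None = None
    z: np.ndarray | None = None
    composite: np.ndarray | None = None

    @property
    def n_dyads(self) -> int:
        return self.raw.shape[0]


def dyad_pairs(n: int) -> np.ndarray:
    """Index pairs (i, j), i < j, in canonical lexicographic order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def dyadic_roi_correlations(ts: RoiTimeSeriesSet) -> SimilarityMatrix:
    """Pearson correlation between every pair of subjects for every ROI.

    Entries where either subject lacks the ROI — or where a series has
    zero variance (flat signal carries no correlation) — are NaN.
    """
    n, r, t = ts.series.shape
    if t < 3:
        raise ValueError("need at least 3 time points")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    pairs = dyad_pairs(n)
    d = len(pairs)
    raw = np.full((d, r), np.nan)

    centered = ts.series - ts.series.mean(axis=2, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=2))  # [N x R]
    zero_var = (norms == 0) & ts.present_mask
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance series treated as missing",
            stacklevel=2,
        )
    usable = ts.present_mask & (norms > 0)

    ii, jj = pairs[:, 0], pairs[:, 1]
    for roi in range(r):
        x = centered[:, roi, :]
        nrm = norms[:, roi]
        ok = usable[ii, roi] & usable[jj, roi]
        if not ok.any():
            continue
        num = np.einsum("dt,dt->d", x[ii[ok]], x[jj[ok]])
        raw[np.nonzero(ok)[0], roi] = np.clip(
            num / (nrm[ii[ok]] * nrm[jj[ok]]), -1.0, 1.0
        )

    ids = ts.subject_ids
    index = tuple((ids[i], ids[j]) for i, j in pairs)
    return SimilarityMatrix(raw=raw, dyad_index=index, roi_names=ts.roi_names)


def impute_missing(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Replace each missing dyad x ROI correlation with that ROI's mean
    correlation over the observed dyads, flagging imputed cells."""
    raw = sim.raw.copy()
    missing = np.isnan(raw)
    dead = missing.all(axis=0)
    if dead.any():
        names = [sim.roi_names[k] for k in np.nonzero(dead)[0]]
        raise ValueError(f"no observed dyads for ROI(s): {names}")
    col_means = np.nanmean(raw, axis=0)
    raw[missing] = np.broadcast_to(col_means, raw.shape)[missing]
    return dataclasses.replace(sim, raw=raw, imputed_flags=missing)


def normalize_per_roi(sim: SimilarityMatrix, ddof: int = 1) -> SimilarityMatrix:
    """z-score each ROI's similarity vector across dyads (mean 0, SD 1).

    Sample SD (ddof=1) by default; population SD available via ddof=0.
    """
    raw = sim.raw
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 dyads to normalize")
    if np.isnan(raw).any():
        raise ValueError("normalize_per_roi requires imputed (complete) data")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=ddof)
    if (sd == 0).any():
        names = [sim.roi_names[k] for k in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance similarity column for ROI(s): {names}")
    return dataclasses.replace(sim, z=(raw - mean) / sd)


def weighted_composite(
    sim: SimilarityMatrix, volumes: pd.DataFrame | Sequence[float] | None = None
) -> SimilarityMatrix:
    """Composite similarity per dyad: weighted mean of the z-scored ROI
    similarities, weights proportional to average ROI volume.

    ``volumes`` may be a DataFrame with a ``volume_mm3`` column indexed by
    ROI name, a plain vector aligned with ``roi_names``, or None for equal
    weights (the unweighted-mean sensitivity mode).
    """
    if sim.z is None:
        raise ValueError("normalize_per_roi must run before weighted_composite")
    r = sim.z.shape[1]
    if volumes is None:
        w = np.ones(r)
    elif isinstance(volumes, pd.DataFrame):
        w = volumes["volume_mm3"].reindex(list(sim.roi_names)).to_numpy(dtype=float)
        if np.isnan(w).any():
            raise KeyError("volumes table is missing some ROI names")
    else:
        w = np.asarray(volumes, dtype=float)
        if w.shape != (r,):
            raise ValueError("volumes vector length must equal number of ROIs")
    if (w < 0).any():
        raise ValueError("volumes must be non-negative")
    if w.sum() <= 0:
        raise ValueError("volumes must have positive total weight")
    comp = sim.z @ (w / w.sum())
    return dataclasses.replace(sim, composite=comp)


def build_dyad_table(
    sim: SimilarityMatrix,
    distances: np.ndarray,
    demographics: pd.DataFrame,
    subject_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the universal dyad-level exchange table.

    One row per unordered pair: social-distance category, a friendship
    indicator (category 1), demographic *dis*similarity controls (1 if the
    two members differ, absolute age gap in years), the composite
    similarity and every per-ROI z-scored similarity.

    ``distances`` is the capped-category matrix aligned with the subject
    order underlying ``sim.dyad_index``; ``demographics`` must cover all
    scanned subjects (extra cohort rows are fine).
    """
    if sim.z is None or sim.composite is None:
        raise ValueError("similarity matrix must be imputed, normalized and composited")
    ids = subject_ids
    if ids is None:
        seen: list[str] = []
        for a, b in sim.dyad_index:
            for s in (a, b):
                if s not in seen:
                    seen.append(s)
        ids = seen
    ids = list(ids)
    absent = [s for s in ids if s not in demographics.index]
    if absent:
        raise KeyError(f"scanned subjects missing from demographics: {absent}")
    pos = {s: k for k, s in enumerate(ids)}
    demo = demographics.loc[ids]

    rows_i = np.array([pos[a] for a, _ in sim.dyad_index])
    rows_j = np.array([pos[b] for _, b in sim.dyad_index])
    dist = np.asarray(distances)
    if dist.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix does not match subject set")
    cat = dist[rows_i, rows_j].astype(int)

    def differs(col: str) -> np.ndarray:
        v = demo[col].to_numpy()
        return (v[rows_i] != v[rows_j]).astype(int)

    age = demo["age"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "subject_i": [a for a, _ in sim.dyad_index],
            "subject_j": [b for _, b in sim.dyad_index],
            "distance": cat,
            "friend": (cat == 1).astype(int),
            "similarity": sim.composite,
            "diff_gender": differs("gender"),
            "diff_ethnicity": differs("ethnicity"),
            "diff_nationality": differs("nationality"),
            "diff_handedness": differs("handedness"),
            "age_diff": np.abs(age[rows_i] - age[rows_j]),
        }
    )
    zcols = pd.DataFrame(
        sim.z, columns=[f"z_{name}" for name in sim.roi_names], index=table.index
    )
    return pd.concat([table, zcols], axis=1)
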