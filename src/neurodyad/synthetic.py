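"""Synthetic cohort generator: nomination networks, demographics, and ROI time series.

The study design being emulated has two parts: a full cohort (~279 people)
answers a roster-based friendship-nomination survey, and a subsample (~42)
is scanned while watching a common video sequence, yielding one mean
response time series per anatomical ROI per subject.  No such data are
publicly deposited, so this module manufactures a cohort with *known*
ground truth: a tunable, planted decay of dyadic neural similarity with
social (geodesic) distance.

Generative model for the time series of subject i, region r:

    x_{i,r}(t) = c_r(t) + sum_k w_{i,k} f_{k,r}(t) + sigma * eps_{i,r}(t)

where ``c_r`` is a stimulus-locked signal common to everyone (it sets the
floor of inter-subject correlation), ``f_{k,r}`` are K latent
"interpretation component" time courses, and the subject weights
``w_{.,k}`` are drawn with dyadic correlation rho^{d(i,j)} in geodesic
distance d — so the expected inter-subject correlation strictly decreases
with social distance whenever rho < 1, and is flat (null) when rho = 1 or
the component variance is zero.

Every random draw descends from one master seed through named substreams,
so each stage can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .network import NominationMatrix, build_graph, geodesic_distances, restrict_distances
from .similarity import RoiTimeSeriesSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "StudyData",
    "roi_labels",
    "generate_demographics",
    "generate_network",
    "generate_volumes",
    "generate_timeseries",
    "simulate_study",
]

# Gyral-based cortical parcellation labels (34 per hemisphere) plus six deep
# gray-matter structures per hemisphere: 2 * (34 + 6) = 80 regions.
CORTICAL_LABELS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)
SUBCORTICAL_LABELS = (
    "thalamus", "caudate", "putamen", "hippocampus", "amygdala", "accumbens",
)

# substream identifiers for seed derivation
_STREAMS = {
    "demographics": 1,
    "network": 2,
    "sample": 3,
    "traits": 4,
    "timeseries": 5,
    "missing": 6,
    "volumes": 7,
}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study's scale: a 279-person cohort, a
    42-subject imaging subsample, 80 ROIs, ~1000 retained volumes after
    run concatenation, directed nomination rate and reciprocity chosen to
    reproduce an any-tie density near 0.146 and dyad-level reciprocity
    near 0.309, and a per-(subject, ROI) dropout rate near 31/3360.
    """

    n_subjects: int = 42
    n_cohort: int = 279
    n_rois: int = 80
    n_timepoints: int = 1000
    n_components: int = 5
    trait_decay: float = 0.5      # rho: dyadic weight correlation per unit distance
    component_sd: float = 1.0     # scale of latent component loadings; 0 = null
    noise_sd: float = 1.0         # sigma
    common_signal_sd: float = 0.5
    tie_base_rate: float = 0.0955       # directed nomination probability
    reciprocity_target: float = 0.309   # target dyad-level reciprocity
    demographic_assortativity: float = 0.3
    spatial_scale: float = 0.15         # latent-space tie-decay length; 0 = none
    tie_prob_cap: float = 0.4           # per-dyad ceiling on the directed rate
    missing_rate: float = 0.0092
    distance_cap: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.trait_decay <= 1):
            raise ValueError("trait_decay must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.component_sd < 0 or self.common_signal_sd < 0:
            raise ValueError("signal scales must be >= 0")
        for name in ("tie_base_rate", "reciprocity_target",
                     "demographic_assortativity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.spatial_scale < 0:
            raise ValueError("spatial_scale must be >= 0")
        if not (0 < self.tie_prob_cap <= 1):
            raise ValueError("tie_prob_cap must be in (0, 1]")
        if self.n_timepoints <= 3:
            raise ValueError("n_timepoints must be > 3")
        if self.n_rois < 1 or self.n_components < 1:
            raise ValueError("n_rois and n_components must be >= 1")
        if self.n_cohort < 2 or not (2 <= self.n_subjects <= self.n_cohort):
            raise ValueError("need 2 <= n_subjects <= n_cohort")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream of the master seed (independent, reproducible)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    true_distance_effect: float  # per-unit-distance drop in expected ROI correlation
    expected_correlation_by_distance: dict[int, float]
    subject_traits: np.ndarray        # [N x K] component weights
    component_timecourses: np.ndarray  # [K x R x T]


def roi_labels(n_rois: int = 80) -> tuple[str, ...]:
    """ROI name list; the 80-region default is two hemispheres of 34 cortical
    plus 6 subcortical labels, otherwise generic numbered labels."""
    if n_rois == 80:
        return tuple(
            f"{hemi}-{name}"
            for hemi in ("lh", "rh")
            for name in CORTICAL_LABELS + SUBCORTICAL_LABELS
        )
    return tuple(f"roi{k:03d}" for k in range(n_rois))


def generate_demographics(config: SyntheticConfig, n: int | None = None) -> pd.DataFrame:
    """Per-subject categorical attributes and age, indexed by subject id.

    Marginals follow the emulated cohort: ~32% female, ages 25-32
    (mean ~28), ~7% left-handed, a handful of ethnicity and nationality
    categories with one majority group each.
    """
    n = config.n_cohort if n is None else int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = config.rng("demographics")
    gender = rng.choice(["F", "M"], size=n, p=[0.32, 0.68])
    ethnicity = rng.choice(["eth1", "eth2", "eth3", "eth4"], size=n,
                           p=[0.55, 0.20, 0.15, 0.10])
    nationality = rng.choice(["nat1", "nat2", "nat3", "nat4", "nat5"], size=n,
                             p=[0.60, 0.15, 0.10, 0.08, 0.07])
    age = np.clip(np.rint(rng.normal(28.0, 1.7, size=n)), 25, 32).astype(int)
    handedness = rng.choice(["L", "R"], size=n, p=[0.07, 0.93])
    return pd.DataFrame(
        {
            "subject_id": [f"S{k:04d}" for k in range(n)],
            "gender": gender,
            "ethnicity": ethnicity,
            "nationality": nationality,
            "age": age,
            "handedness": handedness,
        }
    ).set_index("subject_id")


def _reciprocity_mixture_weight(p: np.ndarray, target: float) -> np.ndarray:
    """Mixing weight phi of the shared-draw component of a dyad's two
    directed ties, solved so that P(mutual | any tie) equals ``target``.

    With probability phi both directions copy one Bernoulli(p) draw, else
    they are independent Bernoulli(p); then
    P(mutual)/P(any) = (phi + (1-phi) p) / (phi + (1-phi)(2-p)).
    Solved per dyad, so the dyad-level reciprocity equals the target even
    when tie probabilities are heterogeneous.  Clipped into [0, 1] where
    the target is unattainable at that p.
    """
    p = np.asarray(p, dtype=float)
    num = target * (2.0 - p) - p
    den = num + (1.0 - target)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return np.clip(phi, 0.0, 1.0)


def generate_network(
    config: SyntheticConfig, demographics: pd.DataFrame | None = None
) -> NominationMatrix:
    """Directed nomination matrix over the cohort.

    Each dyad's two directed ties are a mixture of one shared and two
    independent Bernoulli draws, which controls dyad-level reciprocity
    without changing the directed tie rate.  Sharing a gender multiplies a
    dyad's tie probability by (1 - a + a) vs (1 - a) under assortativity
    a; a = 1 confines all ties to same-gender dyads.  Subjects also carry
    latent 2-D positions with a Gaussian tie-decay kernel of length
    ``spatial_scale``: local clustering stretches geodesic distances the
    way section/friendship-circle structure does in a real cohort
    (a pure Erdős–Rényi graph at this density has almost no dyads beyond
    distance 3).  Weights are renormalized to keep the mean directed rate
    at ``tie_base_rate``.
    """
    if demographics is None:
        demographics = generate_demographics(config)
    n = len(demographics)
    if n < 2:
        raise ValueError("need a cohort of at least 2")
    rng = config.rng("network")
    p = config.tie_base_rate
    a = config.demographic_assortativity

    gender = demographics["gender"].to_numpy()
    same_gender = (gender[:, None] == gender[None, :]).astype(float)
    weight = (1.0 - a) + a * same_gender
    iu = np.triu_indices(n, k=1)
    w = weight[iu]
    if config.spatial_scale > 0:
        pos = rng.random((n, 2))
        dist2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)[iu]
        w = w * np.exp(-dist2 / (2.0 * config.spatial_scale**2))
    mean_w = w.mean() if w.mean() > 0 else 1.0
    cap = config.tie_prob_cap
    p_dyad = np.clip(p * w / mean_w, 0.0, cap)
    if 0 < p < cap:
        # push back mass truncated by the cap so the mean rate stays at p
        for _ in range(8):
            p_dyad = np.clip(p_dyad * p / max(p_dyad.mean(), 1e-12), 0.0, cap)
    if p == 1.0:  # saturated: spatial decay must not dilute the degenerate case
        p_dyad = np.where(w > 0, 1.0, 0.0) if a > 0 else np.ones_like(w)

    phi = _reciprocity_mixture_weight(p_dyad, config.reciprocity_target)
    shared = rng.random(p_dyad.size) < phi
    t_shared = rng.random(p_dyad.size) < p_dyad
    t_fwd = rng.random(p_dyad.size) < p_dyad
    t_rev = rng.random(p_dyad.size) < p_dyad
    fwd = np.where(shared, t_shared, t_fwd)
    rev = np.where(shared, t_shared, t_rev)

    entries = np.zeros((n, n), dtype=np.int8)
    entries[iu] = fwd
    entries.T[iu] = rev
    return NominationMatrix(entries=entries, subject_ids=tuple(demographics.index))


def generate_volumes(config: SyntheticConfig) -> pd.DataFrame:
    """Average ROI volumes (mm^3), log-normal around ~8 cm^3."""
    rng = config.rng("volumes")
    names = roi_labels(config.n_rois)
    vols = np.exp(rng.normal(np.log(8000.0), 0.6, size=config.n_rois))
    return pd.DataFrame({"roi": names, "volume_mm3": vols}).set_index("roi")


def _nearest_correlation_psd(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to PSD by clipping negative eigenvalues,
    then rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((c + c.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    c_psd = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(c_psd), 1e-12, None))
    c_psd = c_psd / np.outer(d, d)
    np.fill_diagonal(c_psd, 1.0)
    return c_psd


def generate_timeseries(
    network_distances: np.ndarray, config: SyntheticConfig
) -> tuple[RoiTimeSeriesSet, GroundTruth]:
    """Simulate per-subject ROI time series over a given distance matrix.

    ``network_distances`` is the (already capped) geodesic distance matrix
    among the scanned subjects; entries must be finite.  Subject component
    weights are drawn from N(0, C) with C = rho^d repaired to the nearest
    unit-diagonal PSD matrix, so dyads at smaller social distance share
    more latent signal.
    """
    d = np.asarray(network_distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.isfinite(d).all():
        raise ValueError("network_distances must be a finite square matrix")
    if n != config.n_subjects:
        raise ValueError("distance matrix size does not match n_subjects")
    rho, k, r, t = (config.trait_decay, config.n_components,
                    config.n_rois, config.n_timepoints)
    sigma, c_sd, w_sd = config.noise_sd, config.common_signal_sd, config.component_sd

    corr = _nearest_correlation_psd(rho ** d)
    vals, vecs = np.linalg.eigh(corr)
    sqrt_corr = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rng_w = config.rng("traits")
    traits = w_sd * (sqrt_corr @ rng_w.standard_normal((n, k)))

    rng_ts = config.rng("timeseries")
    components = rng_ts.standard_normal((k, r, t))
    common = c_sd * rng_ts.standard_normal((r, t))
    noise = sigma * rng_ts.standard_normal((n, r, t))
    series = common[None] + np.einsum("ik,krt->irt", traits, components) + noise

    rng_m = config.rng("missing")
    present = rng_m.random((n, r)) >= config.missing_rate
    # imputation needs >= 1 observed dyad per ROI: keep >= 2 subjects present
    thin = present.sum(axis=0) < 2
    present[:, thin] = True

    # expected inter-subject Pearson correlation at each planted distance
    total_var = c_sd**2 + k * w_sd**2 + sigma**2
    exp_corr = {
        dd: (c_sd**2 + k * w_sd**2 * rho**dd) / total_var
        for dd in range(1, config.distance_cap + 1)
    }
    span = config.distance_cap - 1
    effect = (exp_corr[config.distance_cap] - exp_corr[1]) / span if span else 0.0

    ts = RoiTimeSeriesSet(
        series=series,
        present_mask=present,
        roi_names=roi_labels(r),
        subject_ids=tuple(f"sub{k_:03d}" for k_ in range(n)),
        volumes=None,
    )
    truth = GroundTruth(
        true_distance_effect=float(effect),
        expected_correlation_by_distance=exp_corr,
        subject_traits=traits,
        component_timecourses=components,
    )
    return ts, truth


@dataclasses.dataclass(frozen=True)
class StudyData:
    """One complete simulated study, ready for the analysis pipeline."""

    config: SyntheticConfig
    demographics: pd.DataFrame           # full cohort
    nominations: NominationMatrix        # full cohort
    distances: "np.ndarray"              # capped categories among scanned subjects
    scanned_ids: tuple[str, ...]
    timeseries: RoiTimeSeriesSet
    volumes: pd.DataFrame
    ground_truth: GroundTruth


def simulate_study(config: SyntheticConfig) -> StudyData:
    """Full simulated study: cohort survey, scanned subsample, time series.

    Geodesic distances are computed on the *full-cohort* reciprocal-tie
    graph and then restricted to the scanned subsample (paths through
    unscanned cohort members count), mirroring how social distance is
    defined for an imaging subsample embedded in a larger network.
    """
    demographics = generate_demographics(config)
    nominations = generate_network(config, demographics)
    graph = build_graph(nominations, "reciprocal")
    dres = geodesic_distances(graph, cap=config.distance_cap)

    rng = config.rng("sample")
    idx = np.sort(rng.choice(config.n_cohort, size=config.n_subjects, replace=False))
    scanned = tuple(demographics.index[idx])
    sub = restrict_distances(dres, scanned)

    ts, truth = generate_timeseries(sub.capped_category, config)
    ts = RoiTimeSeriesSet(
        series=ts.series,
        present_mask=ts.present_mask,
        roi_names=ts.roi_names,
        subject_ids=scanned,
        volumes=None,
    )
    volumes = generate_volumes(config)
    return StudyData(
        config=config,
        demographics=demographics,
        nominations=nominations,
        distances=sub.capped_category,
        scanned_ids=scanned,
        timeseries=ts,
        volumes=volumes,
        ground_truth=truth,
    )
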