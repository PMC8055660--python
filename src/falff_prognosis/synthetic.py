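"""Seeded synthetic cohorts for the aphasia-prognosis pipeline.

Real resting-state scans and behavioral batteries for this problem are not
publicly downloadable, so every downstream stage is exercised on generated
cohorts with known ground truth:

* BOLD volumes are built as a sum of spatially compact, approximately
  independent sources (smoothed random blobs) mixed by per-subject time
  courses whose low-frequency power fraction (fALFF) is planted to a known
  target, plus white noise and a constant baseline offset.
* The behavioral battery is a common-factor model (blocks of measures load
  a shared factor), giving the multicollinearity real aphasia batteries
  show, with a small completely-at-random missingness rate (3.3% by
  default) on baseline measures only — outcome columns are never masked.
* Post-treatment outcomes follow a known linear model of the pre-treatment
  score and the planted per-subject fALFF profile, clamped to [0, 1].

All randomness fans out from one integer seed through fixed
``numpy.random.SeedSequence`` spawn keys, so a cohort is reproducible
bit-for-bit and per-subject streams do not shift when other parts of the
configuration change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .bold import Bold4D
from .errors import ConfigurationError
from .falff import DEFAULT_BAND_HZ, component_falff

__all__ = [
    "BATTERY_MEASURES",
    "SourceSet",
    "CohortConfig",
    "SyntheticCohort",
    "make_sources",
    "make_component_timeseries",
    "make_cohort",
]

# The 27-measure aphasia assessment battery (11 assessments). Used as the
# default column roster of the synthetic behavioral table.
BATTERY_MEASURES = [
    "WAB-IC", "WAB-FL", "WAB-CO", "WAB-RE", "WAB-NA",
    "NNB-NC", "NNB-VC", "NNB-NP", "NNB-VP",
    "SCT-C", "SCT-N", "SPPT-C", "SPPT-N",
    "PALPA1",
    "PALPA35-RE", "PALPA35-EX", "PALPA40-HF", "PALPA40-LF",
    "PALPA51-HI", "PALPA51-LI",
    "PPT", "D&P",
    "CIND-WPM", "CIND-MLW", "CIND-MLM",
    "DS-FOR", "DS-BAC",
]

# Seed-fanning domains: rng(seed, domain, *indices) is the only way the
# generator draws randomness.
_DOM_SOURCES = 0
_DOM_SCAN = 1
_DOM_TIMESERIES = 2
_DOM_BEHAVIOR = 3
_DOM_OUTCOME = 4
_DOM_MISSING = 5
_DOM_TARGETS = 6


def _rng(seed: int, domain: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(domain, *indices)))


@dataclass
class SourceSet:
    """Planted spatial sources: compact smoothed blobs on a small 3D grid.

    ``spatial_maps`` is (n_sources, n_voxels) over the flattened grid;
    pairwise spatial correlation is below 0.2 in absolute value by
    construction (the maps are exactly decorrelated and rotated to the
    empirical spatial-independence optimum, so the planted truth is the
    identifiable ground truth of the mixtures built from it).
    """

    spatial_maps: np.ndarray
    grid_dims: tuple[int, int, int]
    support_fraction: float
    smooth_sigma: float

    @property
    def n_sources(self) -> int:
        return self.spatial_maps.shape[0]

    def as_volumes(self) -> np.ndarray:
        return self.spatial_maps.reshape((self.n_sources,) + tuple(self.grid_dims))


def make_sources(
    n_sources: int,
    grid_dims: tuple[int, int, int],
    seed: int,
    support_fraction: float = 0.10,
    smooth_sigma: float = 1.5,
    max_correlation: float = 0.2,
    max_attempts: int = 200,
) -> SourceSet:
    """Draw spatially compact, independent source maps.

    Each map starts as a Gaussian-smoothed white-noise field thresholded to
    its top ``support_fraction`` of voxels (a compact blob with graded
    intensity, zero elsewhere). Maps are drawn sequentially; a candidate
    whose absolute spatial correlation with any accepted blob reaches
    ``max_correlation`` is rejected and redrawn. The accepted blob set is
    then exactly decorrelated (symmetric whitening of the centered maps)
    and rotated to the empirical independence optimum of the InfoMax
    objective. This final rotation perturbs each blob only slightly
    (correlation with the raw blob typically > 0.99) but makes the planted
    maps the exactly identifiable sources of any noiseless mixture built
    from them — without it, ground truth would only be defined up to a
    finite-sample rotation that no decomposition could resolve.
    """
    grid_dims = tuple(int(g) for g in grid_dims)
    n_voxels = int(np.prod(grid_dims))
    if n_sources < 1:
        raise ConfigurationError("n_sources must be >= 1")
    if n_sources > n_voxels / 10:
        raise ConfigurationError(
            f"{n_sources} sources on a {n_voxels}-voxel grid: need n_sources <= n_voxels/10"
        )
    rng = _rng(seed, _DOM_SOURCES)
    maps: list[np.ndarray] = []
    attempts = 0
    while len(maps) < n_sources:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"could not place {n_sources} sources with |r| < {max_correlation} "
                f"on grid {grid_dims} after {max_attempts} draws"
            )
        attempts += 1
        field3d = ndimage.gaussian_filter(rng.standard_normal(grid_dims), sigma=smooth_sigma)
        flat = field3d.ravel()
        k = max(1, int(round(support_fraction * n_voxels)))
        thresh = np.partition(flat, -k)[-k]
        candidate = np.where(flat >= thresh, flat - thresh, 0.0)
        peak = candidate.max()
        if peak <= 0:
            continue
        candidate /= peak
        ok = all(
            abs(np.corrcoef(candidate, m)[0, 1]) < max_correlation for m in maps
        )
        if ok:
            maps.append(candidate)
    M = np.vstack(maps)
    if n_sources > 1:
        # Exact decorrelation, then rotation to the InfoMax independence
        # optimum (see docstring).
        from .ica import infomax_unmix

        Mc = M - M.mean(axis=1, keepdims=True)
        cov = Mc @ Mc.T / (n_voxels - 1)
        evals, evecs = np.linalg.eigh(cov)
        white = evecs @ np.diag(evals**-0.5) @ evecs.T @ Mc
        W = infomax_unmix(white, seed=int(seed) % (2**31), max_iter=3000, tol=1e-12)
        M = W @ white
    return SourceSet(
        spatial_maps=M,
        grid_dims=grid_dims,
        support_fraction=support_fraction,
        smooth_sigma=smooth_sigma,
    )


def make_component_timeseries(
    target_falff: float,
    n_timepoints: int,
    tr_seconds: float,
    seed: int,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    n_tones: int = 8,
    noise_floor: float = 1e-3,
) -> np.ndarray:
    """Synthesize a time course whose realized fALFF hits a target.

    The series is a sum of cosines with random phases at DFT-bin frequencies
    strictly inside the low-frequency band plus a second sum at bin
    frequencies strictly above 0.09 Hz (and below Nyquist), amplitude-ratioed
    so that in-band power / total power equals ``target_falff``, with a tiny
    white-noise floor. Because all tones sit exactly on periodogram bins,
    the realized band-power fraction matches the target to well within 0.02.
    Output is standardized to unit variance.
    """
    f = float(target_falff)
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"target_falff must be in [0, 1]; got {f}")
    T = int(n_timepoints)
    if T < 64:
        raise ConfigurationError("n_timepoints must be >= 64")
    tr = float(tr_seconds)
    nyquist = 0.5 / tr
    lo, hi = band_hz
    if hi >= nyquist:
        raise ConfigurationError(
            f"band ({lo}-{hi} Hz) exceeds Nyquist {nyquist:.4g} Hz at TR={tr}s"
        )
    freqs = np.fft.rfftfreq(T, d=tr)
    in_bins = np.flatnonzero((freqs > lo) & (freqs < hi))
    out_bins = np.flatnonzero((freqs > max(0.09, hi + 1e-12)) & (freqs < nyquist - 1e-12))
    if f > 0 and in_bins.size == 0:
        raise ConfigurationError("no DFT bins strictly inside the low-frequency band")
    if f < 1 and out_bins.size == 0:
        raise ConfigurationError("no DFT bins available above the band for this TR/length")

    rng = _rng(seed, _DOM_TIMESERIES)
    t = np.arange(T) * tr

    def tone_sum(bins: np.ndarray) -> np.ndarray:
        chosen = rng.choice(bins, size=min(n_tones, bins.size), replace=False)
        amps = rng.uniform(0.5, 1.0, size=chosen.size)
        phases = rng.uniform(0, 2 * np.pi, size=chosen.size)
        out = np.zeros(T)
        for b, a, ph in zip(chosen, amps, phases):
            out += a * np.cos(2 * np.pi * freqs[b] * t + ph)
        return out

    series = np.zeros(T)
    if f > 0:
        s_in = tone_sum(in_bins)
        p_in = s_in.var()
        series += s_in
    if f < 1:
        s_out = tone_sum(out_bins)
        p_out = s_out.var()
        if f > 0:
            # scale out-of-band part so p_in / (p_in + c^2 p_out) = f
            c = np.sqrt(p_in * (1 - f) / (f * p_out))
            s_out = c * s_out
        series += s_out
    sd = series.std()
    if sd > 0:
        series = series / sd
    series += noise_floor * rng.standard_normal(T)
    return series / series.std()


def _default_factor_loadings(
    n_measures: int,
    rng: np.random.Generator,
    n_factors: int = 3,
    block_loading: float = 0.6,
    general_loading: float = 0.55,
) -> np.ndarray:
    """General factor plus block factors.

    Every measure loads a general language-ability factor (real batteries
    are globally multicollinear: almost all measures correlate positively),
    and contiguous blocks of measures share an additional specific factor
    (sub-measures of one assessment correlate even more strongly).
    """
    loadings = np.zeros((n_measures, n_factors + 1))
    loadings[:, 0] = general_loading
    edges = np.linspace(0, n_measures, n_factors + 1).astype(int)
    for j in range(n_factors):
        loadings[edges[j] : edges[j + 1], j + 1] = block_loading
    return loadings


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the acquisition this pipeline targets — TR = 2 s BOLD
    series, a 27-measure behavioral battery with 3.3% of baseline cells
    missing completely at random, bounded outcomes driven by the
    pre-treatment score (weight 0.5) and the planted fALFF profile — at a
    desk-scale grid (12 x 12 x 8 voxels, 120 timepoints; the full
    210-volume acquisitions are supported by overriding ``n_timepoints``).
    """

    n_subjects: int = 30
    grid_dims: tuple[int, int, int] = (12, 12, 8)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    n_sources: int = 5
    target_falff: np.ndarray | None = None  # (n_subjects, n_sources); drawn U(0.1, 0.9) if None
    noise_sd: float = 0.1
    baseline_offset: float = 1000.0
    behavioral_factor_loadings: np.ndarray | None = None  # (n_measures, n_factors)
    measure_names: list[str] = field(default_factory=lambda: list(BATTERY_MEASURES))
    missing_rate: float = 0.033
    outcome_weights: np.ndarray | None = None  # [w_pre, w_1..w_K]; default [0.5, 0.8, -0.6, 0.5, ...]
    outcome_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_sources < 1 or self.n_timepoints < 1:
            raise ConfigurationError("counts must be >= 1")
        if len(self.grid_dims) != 3:
            raise ConfigurationError("grid_dims must have 3 entries")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0 or self.outcome_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.target_falff is not None:
            tf = np.asarray(self.target_falff, dtype=float)
            if tf.shape != (self.n_subjects, self.n_sources):
                raise ConfigurationError(
                    f"target_falff must be (n_subjects, n_sources) = "
                    f"({self.n_subjects}, {self.n_sources}); got {tf.shape}"
                )
            if (tf < 0).any() or (tf > 1).any():
                raise ConfigurationError("target_falff entries must be in [0, 1]")


def _default_outcome_weights(n_sources: int) -> np.ndarray:
    # Mixed-sign fALFF weights with a positive sum so that the cohort shows
    # a net treatment gain (post > pre on average), as treated cohorts do.
    base = np.array([1.0, -0.4, 0.8, 0.7, -0.2])
    w = np.resize(base, n_sources)
    return np.concatenate([[0.5], w])


@dataclass
class SyntheticCohort:
    """A generated cohort: scans, ground truth, behavioral table, outcomes."""

    scans: list[Bold4D]
    truth_sources: SourceSet
    truth_falff: np.ndarray  # (n_subjects, n_sources), the planted raw targets
    truth_timeseries: list[np.ndarray]  # per subject, (t, n_sources), unit variance
    behavioral: pd.DataFrame  # subject_id + measures, NaN = missing
    pre_tsm: np.ndarray
    post_tsm: np.ndarray
    config: CohortConfig
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.scans]

    def truth_falff_normalized(self) -> np.ndarray:
        """Planted fALFF profiles standardized to sum to one per subject."""
        return self.truth_falff / self.truth_falff.sum(axis=1, keepdims=True)

    def behavioral_table(self) -> pd.DataFrame:
        """Behavioral-mode model table: battery + pre/post TSM columns."""
        df = self.behavioral.copy()
        df["pre_tsm"] = self.pre_tsm
        df["post_tsm"] = self.post_tsm
        return df

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write scans (.nii.gz + mask), behavioral and outcome CSVs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        mask_path = out / "mask.nii.gz"
        self.scans[0].save(out / f"{self.scans[0].subject_id}_bold.nii.gz", mask_path)
        paths["mask"] = mask_path
        paths[self.scans[0].subject_id] = out / f"{self.scans[0].subject_id}_bold.nii.gz"
        for scan in self.scans[1:]:
            p = out / f"{scan.subject_id}_bold.nii.gz"
            scan.save(p)
            paths[scan.subject_id] = p
        behav = self.behavioral_table()
        bpath = out / "behavioral.csv"
        behav.to_csv(bpath, index=False)
        paths["behavioral"] = bpath
        truth = pd.DataFrame(
            self.truth_falff,
            columns=[f"source_{k + 1:02d}" for k in range(self.truth_falff.shape[1])],
        )
        truth.insert(0, "subject_id", self.subject_ids)
        tpath = out / "truth_falff.csv"
        truth.to_csv(tpath, index=False)
        paths["truth_falff"] = tpath
        return paths


def make_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a validated configuration.

    Each scan is ``sum_k timeseries_k (x) map_k`` plus i.i.d. Gaussian noise
    and a constant baseline offset; outcomes are
    ``clamp_[0,1](w_pre * pre + sum_k w_k * falff_norm_k + eps)`` where
    ``falff_norm`` is the planted fALFF profile standardized to sum to one
    per subject (the same standardization applied to measured features).
    """
    config.validate()
    seed = int(config.seed)
    n, K, T = config.n_subjects, config.n_sources, config.n_timepoints

    sources = make_sources(K, config.grid_dims, seed)
    if config.target_falff is None:
        targets = _rng(seed, _DOM_TARGETS).uniform(0.1, 0.9, size=(n, K))
    else:
        targets = np.asarray(config.target_falff, dtype=float).copy()

    mask = np.ones(config.grid_dims, dtype=bool)
    scans: list[Bold4D] = []
    truth_ts: list[np.ndarray] = []
    for i in range(n):
        tcs = np.column_stack(
            [
                make_component_timeseries(
                    targets[i, k], T, config.tr_seconds, seed=_subseed(seed, i, k)
                )
                for k in range(K)
            ]
        )
        truth_ts.append(tcs)
        data = tcs @ sources.spatial_maps  # (t, n_voxels)
        if config.noise_sd > 0:
            data = data + config.noise_sd * _rng(seed, _DOM_SCAN, i).standard_normal(data.shape)
        vol = data.T.reshape(tuple(config.grid_dims) + (T,)) + config.baseline_offset
        scans.append(
            Bold4D(
                voxels=vol,
                tr_seconds=config.tr_seconds,
                mask=mask,
                subject_id=f"sub-{i + 1:03d}",
            )
        )

    # Behavioral battery: common-factor structure plus unique variance.
    names = list(config.measure_names)
    p = len(names)
    if config.behavioral_factor_loadings is None:
        loadings = _default_factor_loadings(p, _rng(seed, _DOM_BEHAVIOR, 0))
    else:
        loadings = np.asarray(config.behavioral_factor_loadings, dtype=float)
        if loadings.shape[0] != p:
            raise ConfigurationError("behavioral_factor_loadings rows must match measure count")
    rngb = _rng(seed, _DOM_BEHAVIOR, 1)
    factors = rngb.standard_normal((n, loadings.shape[1]))
    unique_sd = np.sqrt(np.clip(1.0 - (loadings**2).sum(axis=1), 0.05, None))
    battery = factors @ loadings.T + rngb.standard_normal((n, p)) * unique_sd
    behavioral = pd.DataFrame(battery, columns=names)
    behavioral.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(n)])

    # MCAR missingness on baseline battery cells only (never on outcomes).
    if config.missing_rate > 0:
        miss = _rng(seed, _DOM_MISSING).random((n, p)) < config.missing_rate
        values = behavioral[names].to_numpy()
        values[miss] = np.nan
        behavioral[names] = values

    # Outcomes: linear in pre-score and the normalized planted fALFF profile.
    rngo = _rng(seed, _DOM_OUTCOME)
    weights = (
        _default_outcome_weights(K)
        if config.outcome_weights is None
        else np.asarray(config.outcome_weights, dtype=float)
    )
    if weights.size != K + 1:
        raise ConfigurationError(f"outcome_weights must have {K + 1} entries (pre + {K} sources)")
    pre = rngo.uniform(0.2, 0.8, size=n)
    falff_norm = targets / targets.sum(axis=1, keepdims=True)
    linear = weights[0] * pre + falff_norm @ weights[1:]
    eps = (
        rngo.normal(0.0, config.outcome_noise_sd, size=n)
        if config.outcome_noise_sd > 0
        else np.zeros(n)
    )
    post = np.clip(linear + eps, 0.0, 1.0)

    return SyntheticCohort(
        scans=scans,
        truth_sources=sources,
        truth_falff=targets,
        truth_timeseries=truth_ts,
        behavioral=behavioral,
        pre_tsm=pre,
        post_tsm=post,
        config=config,
        seed=seed,
    )


def _subseed(seed: int, subject: int, source: int) -> int:
    """Stable per-(subject, source) integer seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_DOM_TIMESERIES, subject, source))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
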