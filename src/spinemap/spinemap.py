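"""Spatial and intensity statistics for potentiated dendritic spines.

This module implements, end to end, the quantitative pipeline used to map
potentiated (reporter-tagged) spines along dendrites:

* a synthetic-data generator that emulates dendrites as 3D curves carrying
  labeled spines, per-spine fluorescence tables and stimulation-locked
  calcium traces, with known ground truth;
* per-spine intensity metrics — Enrichment Index, docked/positive
  classification, relative intensity/volume change time courses, ΔF/F
  integration, and laminar profile alignment/averaging;
* labeled point-pattern statistics — first-neighbor distances with a
  per-dendrite label-shuffle null, the neighbor-rank probability-increase
  curve normalized by (p−1)/(T−1), single-linkage spine-unit clustering at
  a strict <2 μm cutoff, the Separation Index, and a one-sample z-test
  against the reference value 1;
* a simulate → analyze → report pipeline with deterministic seeding and
  tidy CSV/TSV outputs.

The file is sectioned in the order the method runs: configuration,
synthetic data, intensity metrics, spatial statistics, pipeline.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import linkage
from scipy.ndimage import median_filter
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

logger = logging.getLogger("spinemap")

# ---------------------------------------------------------------------------
# Constants (analysis defaults; each traceable to the published procedure)
# ---------------------------------------------------------------------------

#: single-linkage cutoff defining spine units, μm (strict: d < cutoff)
CLUSTER_CUTOFF_UM = 2.0
#: neighbor ranks retained in the probability matrix (N x 20)
N_NEIGHBOR_POSITIONS = 20
#: shuffled label datasets per dendrite for the null distributions
N_SHUFFLES = 5
#: dendrites with positive fraction below this are excluded from the
#: probability-curve analysis (rule i)
MIN_POSITIVE_FRACTION = 0.05
#: circle radius around the PSD center within which a non-docked reporter
#: peak still counts the spine as positive, μm
DOCKED_SEARCH_RADIUS_UM = 0.6
#: post-stimulus frames over which ΔF/F is integrated
DFF_INTEGRATION_FRAMES = 200
#: laminar profiles: anchor (start of stratum pyramidale) target, μm
PROFILE_ANCHOR_TARGET_UM = 100.0
#: laminar profiles: averaging window, μm
PROFILE_BIN_UM = 5.0
#: laminar profiles: total profile length, μm
PROFILE_LENGTH_UM = 325.0

SPINE_TABLE_COLUMNS = [
    "animal_id", "slice_id", "dendrite_id", "region", "condition",
    "spine_id", "x", "y", "z", "arc_position", "positive",
]

REGIONS = ("CA1", "DG")
CONDITIONS = ("home_cage", "novel_context")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic spine-map generator.

    Defaults emulate the study conditions: ~70 spines per ~50 μm dendrite
    (≈1.4 spines/μm), a 20% marginal potentiation rate, and — in clustered
    mode — label clusters with a characteristic arc radius of 2 μm.
    """

    n_animals: int = 2
    n_slices_per_animal: int = 2
    n_dendrites_per_slice: int = 5
    spines_per_dendrite: tuple[int, int] = (50, 90)  # inclusive range or (k, k)
    dendrite_length: float = 50.0          # μm
    spine_lateral_offset_sd: float = 0.5   # μm, isotropic in the normal plane
    label_fraction: float = 0.2
    label_mode: str = "random"             # "random" | "clustered"
    cluster_seed_rate: float = 0.05        # seeds per μm of arc length
    cluster_radius: float = 2.0            # μm (arc distance)
    within_cluster_label_prob: float = 0.9
    baseline_intensity: float = 100.0      # a.u.
    enrichment_factor: float = 3.0         # ≥ 1
    intensity_noise_cv: float = 0.1
    background_level: float = 10.0         # a.u.
    docked_fraction: float = 0.8           # of positive spines
    psd_radius: float = 0.3                # μm, PSD extent
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spines_per_dendrite, int):
            self.spines_per_dendrite = (self.spines_per_dendrite,
                                        self.spines_per_dendrite)
        else:
            self.spines_per_dendrite = tuple(self.spines_per_dendrite)
        self.validate()

    def validate(self) -> None:
        if self.dendrite_length <= 0:
            raise ValueError("dendrite_length must be strictly positive")
        for name in ("label_fraction", "within_cluster_label_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.docked_fraction <= 1.0:
            raise ValueError("docked_fraction must be in [0, 1]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if self.cluster_seed_rate <= 0 or self.cluster_radius <= 0:
            raise ValueError("cluster rates and radii must be positive")
        if self.label_mode not in ("random", "clustered"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        lo, hi = self.spines_per_dendrite
        if lo < 1 or hi < lo:
            raise ValueError("spines_per_dendrite must be a positive count "
                             "or an increasing (low, high) range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spines_per_dendrite"] = list(self.spines_per_dendrite)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in dict(d).items() if k in known})


@dataclass
class RunConfig:
    """One pipeline run: inputs, analysis toggles, parameters, seed."""

    out_dir: str = "run"
    spine_table: str | None = None         # CSV path; None -> simulate
    intensity_table: str | None = None     # optional per-spine intensity CSV
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    distances: bool = True
    probability: bool = True
    clusters: bool = True
    separation: bool = True
    intensity: bool = True
    cutoff_um: float = CLUSTER_CUTOFF_UM
    n_positions: int = N_NEIGHBOR_POSITIONS
    n_shuffles: int = N_SHUFFLES
    rank_mode: str = "euclidean"           # "euclidean" | "ordinal"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "generator" in d and not isinstance(d["generator"], GeneratorConfig):
            d["generator"] = GeneratorConfig.from_dict(d["generator"] or {})
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Synthetic data: dendrites, spine maps, intensity tables, traces
# ---------------------------------------------------------------------------

@dataclass
class DendriteGeometry:
    """A dendrite backbone: an ordered 3D polyline of known arc length."""

    dendrite_id: str
    slice_id: str
    animal_id: str
    region: str
    condition: str
    backbone: np.ndarray       # (n, 3) points, μm
    arc: np.ndarray            # (n,) cumulative arc length, μm


def _dendrite_backbone(length: float, rng: np.random.Generator,
                       step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth 3D curve of total arc length ``length``.

    Built by integrating a slowly wandering unit tangent; curvature is mild
    so neighbor order along the arc tracks 3D proximity, as for real
    dendritic segments at this scale.
    """
    n_steps = max(2, int(np.ceil(length / step)))
    t = rng.standard_normal(3)
    t /= np.linalg.norm(t)
    pts = [np.zeros(3)]
    seg = length / n_steps
    for _ in range(n_steps):
        t = t + 0.1 * rng.standard_normal(3)   # small wander -> gentle curvature
        t /= np.linalg.norm(t)
        pts.append(pts[-1] + seg * t)
    backbone = np.asarray(pts)
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(backbone, axis=0), axis=1))])
    return backbone, arc


def _point_on_backbone(geom: DendriteGeometry, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated 3D point and unit tangent at arc position ``s``."""
    arc, bb = geom.arc, geom.backbone
    s = float(np.clip(s, 0.0, arc[-1]))
    i = int(np.clip(np.searchsorted(arc, s) - 1, 0, len(arc) - 2))
    frac = (s - arc[i]) / (arc[i + 1] - arc[i])
    point = bb[i] + frac * (bb[i + 1] - bb[i])
    tangent = bb[i + 1] - bb[i]
    tangent = tangent / np.linalg.norm(tangent)
    return point, tangent


def _normal_plane_offset(tangent: np.ndarray, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Isotropic Gaussian offset (SD ``sd`` per axis) in the plane ⟂ tangent."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(tangent @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(tangent, ref)
    u /= np.linalg.norm(u)
    v = np.cross(tangent, u)
    a, b = rng.standard_normal(2) * sd
    return a * u + b * v


def _clustered_labels(arc_positions: np.ndarray, length: float,
                      cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Seed-and-radius (Matérn-like) labeling along arc length.

    Cluster seeds are a Poisson process of rate ``cluster_seed_rate``; spines
    within ``cluster_radius`` (arc distance) of a seed are labeled with
    ``within_cluster_label_prob``; the residual rate for uncovered spines is
    solved so the expected marginal positive fraction equals
    ``label_fraction`` (coverage from the Poisson void probability).
    """
    n_seeds = rng.poisson(cfg.cluster_seed_rate * length)
    seeds = rng.uniform(0.0, length, size=n_seeds)
    if n_seeds:
        covered = (np.abs(arc_positions[:, None] - seeds[None, :])
                   <= cfg.cluster_radius).any(axis=1)
    else:
        covered = np.zeros(arc_positions.shape, dtype=bool)
    # expected covered fraction, ignoring edge effects
    cov = 1.0 - np.exp(-cfg.cluster_seed_rate * 2.0 * cfg.cluster_radius)
    if cov >= 1.0 - 1e-12:
        residual = cfg.within_cluster_label_prob
    else:
        residual = (cfg.label_fraction
                    - cov * cfg.within_cluster_label_prob) / (1.0 - cov)
    residual = float(np.clip(residual, 0.0, 1.0))
    p_label = np.where(covered, cfg.within_cluster_label_prob, residual)
    return (rng.uniform(size=arc_positions.shape) < p_label).astype(int)


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[pd.DataFrame, list[DendriteGeometry]]:
    """Generate a spine table and its dendrite geometries.

    Returns a tidy DataFrame with :data:`SPINE_TABLE_COLUMNS` (one row per
    spine, ordered along each dendrite) and the list of backbones. Fully
    deterministic for a fixed ``rng_seed``: each dendrite draws from a
    substream derived from ``(rng_seed, dendrite index)``.
    """
    config.validate()
    rows: list[dict] = []
    geoms: list[DendriteGeometry] = []
    dendrite_counter = 0
    for a in range(config.n_animals):
        for s in range(config.n_slices_per_animal):
            for d in range(config.n_dendrites_per_slice):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.rng_seed, dendrite_counter]))
                region = REGIONS[a % len(REGIONS)]
                condition = CONDITIONS[s % len(CONDITIONS)]
                animal_id = f"animal{a:02d}"
                slice_id = f"{animal_id}_slice{s:02d}"
                dendrite_id = f"{slice_id}_dend{d:02d}"
                backbone, arc = _dendrite_backbone(config.dendrite_length, rng)
                geom = DendriteGeometry(dendrite_id, slice_id, animal_id,
                                        region, condition, backbone, arc)
                geoms.append(geom)

                lo, hi = config.spines_per_dendrite
                n_spines = int(rng.integers(lo, hi + 1))
                arc_pos = np.sort(rng.uniform(0.0, config.dendrite_length,
                                              size=n_spines))
                xyz = np.empty((n_spines, 3))
                for i, sp in enumerate(arc_pos):
                    point, tangent = _point_on_backbone(geom, sp)
                    xyz[i] = point + _normal_plane_offset(
                        tangent, config.spine_lateral_offset_sd, rng)

                if config.label_mode == "random":
                    labels = (rng.uniform(size=n_spines)
                              < config.label_fraction).astype(int)
                else:
                    labels = _clustered_labels(arc_pos, config.dendrite_length,
                                               config, rng)

                for i in range(n_spines):
                    rows.append(dict(
                        animal_id=animal_id, slice_id=slice_id,
                        dendrite_id=dendrite_id, region=region,
                        condition=condition, spine_id=f"{dendrite_id}_s{i:03d}",
                        x=xyz[i, 0], y=xyz[i, 1], z=xyz[i, 2],
                        arc_position=arc_pos[i], positive=int(labels[i])))
                dendrite_counter += 1
    table = pd.DataFrame(rows, columns=SPINE_TABLE_COLUMNS)
    return table, geoms


def generate_intensity_table(table: pd.DataFrame,
                             config: GeneratorConfig) -> pd.DataFrame:
    """Per-spine intensity records matching a spine table.

    Positive spines receive a spine-region mean of ``baseline_intensity ×
    enrichment_factor`` (multiplicative noise, CV ``intensity_noise_cv``);
    negative spines and all shaft regions receive ``baseline_intensity``.
    A ``docked_fraction`` of positive spines gets its reporter peak inside
    the PSD extent; the rest peak outside it but within 0.6 μm of the PSD
    center. Negative spines carry no peak (non-expressing).
    """
    if table.empty:
        raise ValueError("spine table is empty")
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, 2**20]))
    cv = config.intensity_noise_cv

    def noisy(mean: float, n: int) -> np.ndarray:
        if cv == 0:
            return np.full(n, mean)
        return mean * (1.0 + cv * rng.standard_normal(n))

    n = len(table)
    pos = table["positive"].to_numpy().astype(bool)
    spine_mean = np.where(
        pos,
        noisy(config.baseline_intensity * config.enrichment_factor, n),
        noisy(config.baseline_intensity, n))
    shaft_mean = noisy(config.baseline_intensity, n)
    # intensities sit on top of the shared background level
    spine_mean = spine_mean + config.background_level
    shaft_mean = shaft_mean + config.background_level

    xyz = table[["x", "y", "z"]].to_numpy()
    docked = pos & (rng.uniform(size=n) < config.docked_fraction)
    peak = np.full((n, 3), np.nan)
    for i in range(n):
        if not pos[i]:
            continue
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if docked[i]:
            r = rng.uniform(0.0, config.psd_radius)
        else:
            r = rng.uniform(config.psd_radius, DOCKED_SEARCH_RADIUS_UM)
        peak[i] = xyz[i] + r * direction

    out = pd.DataFrame({
        "spine_id": table["spine_id"].to_numpy(),
        "dendrite_id": table["dendrite_id"].to_numpy(),
        "channel": "cherry",
        "spine_region_mean": spine_mean,
        "shaft_region_mean": shaft_mean,
        "background": config.background_level,
        "dendrite_mean": config.baseline_intensity,
        "psd_x": xyz[:, 0], "psd_y": xyz[:, 1], "psd_z": xyz[:, 2],
        "psd_radius": config.psd_radius,
        "peak_x": peak[:, 0], "peak_y": peak[:, 1], "peak_z": peak[:, 2],
        "psd_integrated": np.where(
            pos, noisy(config.baseline_intensity * config.enrichment_factor, n), 0.0),
        "filler_integrated": noisy(config.baseline_intensity, n),
        "expressing": pos.astype(int),
        "docked_truth": docked.astype(int),
    })
    return out


@dataclass
class TimeTrace:
    """Frame-indexed fluorescence samples with stimulus bookkeeping."""

    values: np.ndarray                 # a.u., ordered frames
    frame_period_ms: float = 20.0
    dark_level: float = 0.0
    stimulus_frame: int = 50
    baseline_window: tuple[int, int] | None = None   # [start, stop) frames

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not 0 <= self.stimulus_frame < len(self.values):
            raise ValueError("stimulus_frame outside trace")
        if self.baseline_window is None:
            self.baseline_window = (0, self.stimulus_frame)
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.stimulus_frame):
            raise ValueError("baseline_window must precede stimulus_frame")


def generate_trace(kind: str, *, n_frames: int = 500, stimulus_frame: int = 50,
                   baseline: float = 100.0, dark_level: float = 0.0,
                   amplitude: float = 0.0, tau: float = 40.0,
                   event_rate: float = 0.0, noise_sd: float = 0.0,
                   frame_period_ms: float = 20.0,
                   rng: np.random.Generator | None = None) -> TimeTrace:
    """Synthetic stimulation-locked fluorescence trace.

    ``flat``: constant baseline. ``step_decay``: exponential transient of
    peak ``amplitude`` (a.u.) and time constant ``tau`` (frames) starting at
    the first post-stimulus frame. ``event``: Poisson-timed decaying
    transients at ``event_rate`` per frame. Gaussian noise optional.
    """
    if kind not in ("flat", "step_decay", "event"):
        raise ValueError(f"unknown trace kind {kind!r}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if n_frames < stimulus_frame + 1:
        raise ValueError("trace must extend past the stimulus frame")
    rng = rng or np.random.default_rng(0)
    frames = np.arange(n_frames)
    values = np.full(n_frames, baseline, dtype=float)
    if kind == "step_decay":
        onset = stimulus_frame + 1
        k = frames[onset:] - onset
        values[onset:] += amplitude * np.exp(-k / tau)
    elif kind == "event":
        n_events = rng.poisson(event_rate * n_frames)
        for t0 in np.sort(rng.integers(0, n_frames, size=n_events)):
            k = frames[t0:] - t0
            values[t0:] += amplitude * np.exp(-k / tau)
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal(n_frames)
    return TimeTrace(values + dark_level, frame_period_ms=frame_period_ms,
                     dark_level=dark_level, stimulus_frame=stimulus_frame)


# ---------------------------------------------------------------------------
# Intensity metrics
# ---------------------------------------------------------------------------

class DockedClass(str, enum.Enum):
    DOCKED = "docked"
    POSITIVE_NOT_DOCKED = "positive_not_docked"
    NEGATIVE = "negative"


@dataclass
class SpineIntensityRecord:
    """Region statistics for one spine in one channel.

    ``shaft_region_mean`` is measured on the dendritic shaft 1–2 μm (arc
    distance) from the spine junction; ``background`` is one scalar per
    image, supplied upstream. The PSD extent is an explicit radius around
    ``psd_center`` — the boundary is an input, never inferred here.
    """

    spine_id: str
    channel: str = "cherry"
    spine_region_mean: float = np.nan
    shaft_region_mean: float = np.nan
    background: float = 0.0
    dendrite_mean: float = np.nan
    psd_center: np.ndarray | None = None
    psd_radius: float = np.nan
    peak_location: np.ndarray | None = None
    psd_integrated: float = np.nan
    filler_integrated: float = np.nan
    expressing: bool = True


def enrichment_index(rec: SpineIntensityRecord) -> float:
    """Enrichment Index: background-subtracted spine/shaft intensity ratio.

    EI = (spine_region_mean − background) / (shaft_region_mean − background).
    Only expressing spines are meaningful here (the caller filters). A
    non-positive denominator makes the record invalid.
    """
    denom = rec.shaft_region_mean - rec.background
    if not denom > 0:
        raise ValueError(
            f"spine {rec.spine_id}: shaft − background = {denom} is not > 0")
    return (rec.spine_region_mean - rec.background) / denom


def homer_or_sep_enrichment(rec: SpineIntensityRecord) -> float:
    """PSD-integrated intensity normalized by the dendrite mean.

    Used identically for PSD-scaffold (Homer1c) content and for surface-AMPAR
    (SEP-GluA1) enrichment. Non-expressing spines are assigned 0.
    """
    if not rec.expressing:
        return 0.0
    if not rec.dendrite_mean > 0:
        raise ValueError(f"spine {rec.spine_id}: dendrite_mean must be > 0")
    return rec.psd_integrated / rec.dendrite_mean


def classify_docked(rec: SpineIntensityRecord) -> DockedClass:
    """Classify a spine by reporter-peak position relative to its PSD.

    docked: peak inside the PSD extent; positive_not_docked: outside the
    extent but within 0.6 μm of the PSD center; negative otherwise
    (including spines with no detectable peak).
    """
    if rec.peak_location is None or np.any(np.isnan(rec.peak_location)):
        return DockedClass.NEGATIVE
    if rec.psd_center is None:
        raise ValueError(f"spine {rec.spine_id}: psd_center undefined")
    d = float(np.linalg.norm(np.asarray(rec.peak_location, float)
                             - np.asarray(rec.psd_center, float)))
    if d <= rec.psd_radius:
        return DockedClass.DOCKED
    if d <= DOCKED_SEARCH_RADIUS_UM:
        return DockedClass.POSITIVE_NOT_DOCKED
    return DockedClass.NEGATIVE


@dataclass
class TimepointSeries:
    """Intensities of one spine across uncaging timepoints (minutes).

    ``i_g`` is the filler (EGFP) integrated density; if ``dendrite_mean``
    is given, i_g is divided by it per timepoint before any change is
    computed (volume normalization).
    """

    timepoints: np.ndarray                  # minutes relative to uncaging
    i_c: np.ndarray                         # reporter channel, a.u.
    i_g: np.ndarray                         # filler channel, a.u.
    dendrite_mean: np.ndarray | None = None
    reference_timepoint: float = -5.0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, float)
        self.i_c = np.asarray(self.i_c, float)
        self.i_g = np.asarray(self.i_g, float)
        if self.reference_timepoint not in self.timepoints:
            raise ValueError("reference timepoint missing from series")


def relative_change(series: TimepointSeries, channel: str, t: float) -> float:
    """Relative intensity change at timepoint ``t`` vs the −5′ reference.

    ΔCh/Ch uses the reporter channel: [I_c(t) − I_c(−5′)] / I_c(−5′).
    ΔV/V uses the filler channel after dendrite normalization, analogously.
    """
    if channel == "cherry":
        values = series.i_c
    elif channel == "filler":
        values = series.i_g
        if series.dendrite_mean is not None:
            values = values / np.asarray(series.dendrite_mean, float)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    ref = values[series.timepoints == series.reference_timepoint][0]
    if not ref > 0:
        raise ValueError("reference intensity must be positive")
    idx = np.flatnonzero(series.timepoints == t)
    if idx.size == 0:
        raise ValueError(f"timepoint {t} not in series")
    return float((values[idx[0]] - ref) / ref)


def integrate_dff(trace: TimeTrace,
                  n_frames: int = DFF_INTEGRATION_FRAMES
                  ) -> tuple[float, np.ndarray]:
    """ΔF/F series and its integral over the first post-stimulus frames.

    After dark-level subtraction, F0 is the mean over the baseline window
    and ΔF/F(k) = (F(k) − F0)/F0. Returns ``(integral, dff)`` where the
    integral sums frames stimulus_frame+1 .. stimulus_frame+n_frames and
    ``dff`` is the full per-frame series.
    """
    if len(trace.values) < trace.stimulus_frame + n_frames + 1:
        raise ValueError("trace too short for requested integration window")
    f = trace.values - trace.dark_level
    b0, b1 = trace.baseline_window
    f0 = float(np.mean(f[b0:b1]))
    if not f0 > 0:
        raise ValueError("baseline F0 must be positive after dark subtraction")
    dff = (f - f0) / f0
    s = trace.stimulus_frame
    integral = float(np.sum(dff[s + 1:s + 1 + n_frames]))
    return integral, dff


@dataclass
class StratumProfile:
    """One laminar intensity profile along a line crossing the strata.

    ``positions`` are μm along a 325 μm line at a common sampling step;
    ``anchor`` is the position (μm) of the start of the stratum pyramidale
    identified in the DAPI channel.
    """

    positions: np.ndarray
    intensity: np.ndarray
    anchor: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensity = np.asarray(self.intensity, float)
        if not (self.positions[0] <= self.anchor <= self.positions[-1]):
            raise ValueError("anchor lies outside the profile")


def align_and_average_profiles(profiles: Sequence[StratumProfile],
                               baseline: float | Sequence[float] = 0.0,
                               bin_um: float = PROFILE_BIN_UM,
                               anchor_target: float = PROFILE_ANCHOR_TARGET_UM,
                               smooth: bool = False
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Align profiles on their anatomical anchor, bin, average, normalize.

    Each profile is shifted so its anchor sits at ``anchor_target`` (100 μm),
    its baseline subtracted, samples averaged in ``bin_um`` windows, then
    profiles are averaged pointwise over their common support and the result
    divided by its maximum. Returns ``(bin_centers, averaged)``.

    ``smooth`` applies a display-only running median (window = 1% of the
    binned samples) to the averaged profile.
    """
    if not profiles:
        raise ValueError("empty profile set")
    baselines = (np.full(len(profiles), baseline, float)
                 if np.isscalar(baseline) else np.asarray(baseline, float))
    steps = {round(float(np.diff(p.positions).mean()), 9) for p in profiles}
    if len(steps) != 1:
        raise ValueError("profiles must share a common sampling step")

    binned = []
    for prof, base in zip(profiles, baselines):
        shifted = prof.positions - prof.anchor + anchor_target
        vals = prof.intensity - base
        # bin by mean into fixed windows of the aligned coordinate
        idx = np.floor(shifted / bin_um).astype(int)
        centers = (np.unique(idx) + 0.5) * bin_um
        means = np.array([vals[idx == i].mean() for i in np.unique(idx)])
        binned.append(pd.Series(means, index=np.round(centers, 6)))
    df = pd.concat(binned, axis=1, join="inner")
    if df.empty:
        raise ValueError("profiles have no common aligned support")
    avg = df.mean(axis=1)
    if smooth and len(avg) > 2:
        w = max(3, int(round(0.01 * len(avg))) | 1)
        avg = pd.Series(median_filter(avg.to_numpy(), size=w, mode="nearest"),
                        index=avg.index)
    peak = avg.max()
    if peak <= 0:
        raise ValueError("averaged profile has no positive peak to normalize on")
    avg = avg / peak
    return avg.index.to_numpy(), avg.to_numpy()


# ---------------------------------------------------------------------------
# Spatial statistics on labeled spine patterns
# ---------------------------------------------------------------------------

@dataclass
class LabeledSpinePattern:
    """Ordered spines of one dendrite: 3D positions + binary labels."""

    dendrite_id: str
    positions: np.ndarray          # (T, 3) μm, in along-dendrite order
    labels: np.ndarray             # (T,) int {0,1}; 1 = potentiated
    slice_id: str = ""
    region: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, int).ravel()
        if len(self.positions) != len(self.labels):
            raise ValueError("positions and labels differ in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def T(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return int(self.labels.sum())

    def with_labels(self, labels: np.ndarray) -> "LabeledSpinePattern":
        return dataclasses.replace(self, labels=np.asarray(labels, int))


def patterns_from_table(table: pd.DataFrame) -> list[LabeledSpinePattern]:
    """Split a spine table into per-dendrite labeled patterns.

    Rows are ordered by ``arc_position`` when present (the along-dendrite
    order) and by row order otherwise.
    """
    missing = set(SPINE_TABLE_COLUMNS) - {"arc_position"} - set(table.columns)
    if missing:
        raise ValueError(
            "spine table is missing columns "
            f"{sorted(missing)}; expected header {SPINE_TABLE_COLUMNS}")
    patterns = []
    for dend_id, g in table.groupby("dendrite_id", sort=True):
        if "arc_position" in g.columns:
            g = g.sort_values("arc_position", kind="stable")
        patterns.append(LabeledSpinePattern(
            dendrite_id=str(dend_id),
            positions=g[["x", "y", "z"]].to_numpy(),
            labels=g["positive"].to_numpy(),
            slice_id=str(g["slice_id"].iloc[0]),
            region=str(g["region"].iloc[0]),
            condition=str(g["condition"].iloc[0])))
    return patterns


def pairwise_distances(pattern: LabeledSpinePattern) -> np.ndarray:
    """Symmetric 3D Euclidean distance matrix between all spines, μm."""
    if pattern.T < 2:
        raise ValueError("need at least 2 spines for pairwise distances")
    return squareform(pdist(pattern.positions))


@dataclass
class NeighborDistanceResult:
    """First-neighbor distances for each potentiated spine of one dendrite.

    ``d_pp``/``d_pn`` are NaN where undefined (fewer than 2 positives, or no
    negative spine in the dendrite); ``n_skipped`` counts those cases.
    """

    dendrite_id: str
    spine_index: np.ndarray        # indices of positive spines in the pattern
    d_pp: np.ndarray
    d_pn: np.ndarray
    n_skipped_pp: int = 0
    n_skipped_pn: int = 0


def first_neighbor_distances(pattern: LabeledSpinePattern
                             ) -> NeighborDistanceResult:
    """d_PP and d_PN for every potentiated spine of a dendrite.

    d_PP = min 3D distance to another potentiated spine; d_PN = min distance
    to a non-potentiated spine; both within the same dendrite only.
    """
    pos_idx = np.flatnonzero(pattern.labels == 1)
    if pos_idx.size == 0 or pattern.T < 2:
        return NeighborDistanceResult(pattern.dendrite_id, pos_idx,
                                      np.empty(0), np.empty(0))
    dm = pairwise_distances(pattern)
    neg_idx = np.flatnonzero(pattern.labels == 0)
    d_pp = np.full(pos_idx.size, np.nan)
    d_pn = np.full(pos_idx.size, np.nan)
    for k, i in enumerate(pos_idx):
        others = pos_idx[pos_idx != i]
        if others.size:
            d_pp[k] = dm[i, others].min()
        if neg_idx.size:
            d_pn[k] = dm[i, neg_idx].min()
    n_skip_pp = int(np.isnan(d_pp).sum())
    n_skip_pn = int(np.isnan(d_pn).sum())
    if n_skip_pp or n_skip_pn:
        logger.debug("%s: skipped %d d_PP and %d d_PN (undefined neighbor set)",
                     pattern.dendrite_id, n_skip_pp, n_skip_pn)
    return NeighborDistanceResult(pattern.dendrite_id, pos_idx, d_pp, d_pn,
                                  n_skip_pp, n_skip_pn)


@dataclass
class ShuffleNull:
    """Label-shuffle null for one dendrite: positions fixed, labels permuted."""

    dendrite_id: str
    n_shuffles: int
    results: list[NeighborDistanceResult]

    def pooled_d_pp(self) -> np.ndarray:
        return np.concatenate([r.d_pp for r in self.results]) if self.results \
            else np.empty(0)

    def pooled_d_pn(self) -> np.ndarray:
        return np.concatenate([r.d_pn for r in self.results]) if self.results \
            else np.empty(0)


def shuffle_null(pattern: LabeledSpinePattern, n_shuffles: int = N_SHUFFLES,
                 rng: np.random.Generator | int | None = None) -> ShuffleNull:
    """First-neighbor distances under random label permutation.

    Each shuffle permutes the label vector uniformly over the dendrite's
    fixed spine positions (T and p preserved) and recomputes d_PP/d_PN.
    Deterministic under a fixed seed.
    """
    if pattern.p < 1:
        raise ValueError("need at least one positive spine to shuffle")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    results = []
    for _ in range(n_shuffles):
        shuffled = pattern.with_labels(rng.permutation(pattern.labels))
        results.append(first_neighbor_distances(shuffled))
    return ShuffleNull(pattern.dendrite_id, n_shuffles, results)


@dataclass
class ProbabilityCurve:
    """Per-dendrite probability of label positivity at neighbor ranks 1..n.

    ``expected`` is the exchangeable-label value (p−1)/(T−1); ``increase``
    is probability / expected, the quantity tested against 1.
    """

    dendrite_id: str
    probability: np.ndarray        # (n_positions,)
    expected: float
    increase: np.ndarray
    n_focal: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, len(self.probability) + 1)


def _neighbor_ranking(pattern: LabeledSpinePattern, focal: int,
                      rank_mode: str) -> np.ndarray:
    """Indices of all other spines sorted by rank from the focal spine.

    ``euclidean``: 3D distance to the focal spine, ties broken by order
    along the dendrite. ``ordinal``: absolute ordinal offset along the
    dendrite (either side eligible), ties broken toward the earlier spine.
    """
    others = np.flatnonzero(np.arange(pattern.T) != focal)
    if rank_mode == "euclidean":
        d = np.linalg.norm(pattern.positions[others]
                           - pattern.positions[focal], axis=1)
        order = np.lexsort((others, d))
    elif rank_mode == "ordinal":
        off = np.abs(others - focal)
        order = np.lexsort((others, off))
    else:
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    return others[order]


def neighbor_probability_curve(pattern: LabeledSpinePattern,
                               n_positions: int = N_NEIGHBOR_POSITIONS,
                               rank_mode: str = "euclidean"
                               ) -> ProbabilityCurve:
    """Neighbor-rank positivity probabilities for one dendrite.

    For each potentiated focal spine, the ``n_positions`` nearest other
    spines (both directions along the dendrite eligible) form one row of an
    N×n matrix of labels; probability(i) is the column-i positive fraction
    and increase(i) = probability(i) / [(p−1)/(T−1)].
    """
    if pattern.T < n_positions + 1:
        raise ValueError(
            f"{pattern.dendrite_id}: T={pattern.T} cannot fill "
            f"{n_positions} neighbor positions")
    if pattern.p < 2:
        raise ValueError(f"{pattern.dendrite_id}: need p >= 2 positives")
    focal_idx = np.flatnonzero(pattern.labels == 1)
    matrix = np.empty((focal_idx.size, n_positions), dtype=int)
    for r, i in enumerate(focal_idx):
        ranked = _neighbor_ranking(pattern, i, rank_mode)[:n_positions]
        matrix[r] = pattern.labels[ranked]
    probability = matrix.mean(axis=0)
    expected = (pattern.p - 1) / (pattern.T - 1)
    return ProbabilityCurve(pattern.dendrite_id, probability, expected,
                            probability / expected, focal_idx.size)


def apply_exclusions(patterns: Iterable[LabeledSpinePattern],
                     min_fraction: float = MIN_POSITIVE_FRACTION,
                     n_positions: int = N_NEIGHBOR_POSITIONS
                     ) -> tuple[list[LabeledSpinePattern], list[dict]]:
    """Exclusion rules for the probability-curve analysis only.

    Drops dendrites whose positive fraction is below ``min_fraction``
    (rule i) or that cannot provide a whole set of ``n_positions`` neighbors
    (rule ii). Other statistics keep all dendrites. Returns the retained
    patterns and a log of exclusions with their rule.
    """
    retained, excluded = [], []
    for pat in patterns:
        if pat.T == 0 or pat.p / max(pat.T, 1) < min_fraction:
            excluded.append({"dendrite_id": pat.dendrite_id, "rule": "i",
                             "reason": f"positive fraction "
                                       f"{pat.p}/{pat.T} < {min_fraction}"})
        elif pat.T < n_positions + 1:
            excluded.append({"dendrite_id": pat.dendrite_id, "rule": "ii",
                             "reason": f"T={pat.T} cannot define "
                                       f"{n_positions} neighbors"})
        elif pat.p < 2:
            # (p-1)/(T-1) = 0: the increase is undefined; subsumed by rule i
            # in practice, kept explicit for tiny dendrites
            excluded.append({"dendrite_id": pat.dendrite_id, "rule": "i",
                             "reason": "fewer than 2 positive spines"})
        else:
            retained.append(pat)
    for e in excluded:
        logger.info("excluded %(dendrite_id)s (rule %(rule)s): %(reason)s", e)
    return retained, excluded


def ztest_vs_one(values: Sequence[float]) -> tuple[float, float]:
    """One-sample z-test of the mean against the reference value 1.

    z = (mean − 1)/(sd/√n) with the standard-normal reference; two-sided p.
    A degenerate sample that is identically 1 returns (0, 1); any other
    zero-variance sample is an error.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values for the z-test")
    sd = v.std(ddof=1)
    if sd == 0:
        if np.all(v == 1.0):
            return 0.0, 1.0
        raise ValueError("zero variance with mean != 1")
    z = (v.mean() - 1.0) / (sd / np.sqrt(v.size))
    return float(z), float(2.0 * norm.sf(abs(z)))


@dataclass
class ClusterAssignment:
    """Spine units of one dendrite's potentiated spines.

    ``unit_id[k]`` is the unit of the k-th positive spine; units of size ≥ 2
    are clusters, singletons are units of dimension 1.
    """

    dendrite_id: str
    spine_index: np.ndarray        # indices of positive spines in the pattern
    unit_id: np.ndarray            # (p,) consecutive ints starting at 0
    cutoff: float

    @property
    def unit_sizes(self) -> np.ndarray:
        return np.bincount(self.unit_id) if self.unit_id.size else np.empty(0, int)

    @property
    def n_units(self) -> int:
        return int(self.unit_id.max()) + 1 if self.unit_id.size else 0


def cluster_single_linkage(pattern: LabeledSpinePattern,
                           cutoff: float = CLUSTER_CUTOFF_UM
                           ) -> ClusterAssignment:
    """Single-linkage spine units at a strict distance cutoff.

    Two potentiated spines share a unit iff they are connected through a
    chain of pairwise 3D distances strictly below ``cutoff``. The dendrogram
    comes from scipy's single-linkage; the cut keeps only merges whose
    height is < cutoff, so a pair at exactly the cutoff stays separate.
    """
    pos_idx = np.flatnonzero(pattern.labels == 1)
    p = pos_idx.size
    if p < 1:
        raise ValueError("need at least one positive spine")
    if p == 1:
        return ClusterAssignment(pattern.dendrite_id, pos_idx,
                                 np.zeros(1, int), cutoff)
    Z = linkage(pdist(pattern.positions[pos_idx]), method="single")
    # union-find over the merge list, joining only strictly-below-cutoff merges
    parent = list(range(2 * p - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m, (a, b, height, _) in enumerate(Z):
        if height < cutoff:
            node = p + m
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = [find(i) for i in range(p)]
    _, unit_id = np.unique(roots, return_inverse=True)
    return ClusterAssignment(pattern.dendrite_id, pos_idx,
                             unit_id.astype(int), cutoff)


def unit_statistics(assignments: Sequence[ClusterAssignment]) -> dict:
    """Pooled spine-unit summary across dendrites.

    Mean unit size (clusters and single spines together), 5th/95th
    percentiles of cluster dimension (units of size ≥ 2 only), and the
    fraction of potentiated spines belonging to a cluster.
    """
    sizes = np.concatenate([a.unit_sizes for a in assignments]) \
        if assignments else np.empty(0, int)
    if sizes.size == 0:
        raise ValueError("no spine units")
    cluster_sizes = sizes[sizes >= 2]
    total_pos = sizes.sum()
    return {
        "n_units": int(sizes.size),
        "n_clusters": int(cluster_sizes.size),
        "mean_unit_size": float(sizes.mean()),
        "cluster_size_p5": (float(np.percentile(cluster_sizes, 5))
                            if cluster_sizes.size else np.nan),
        "cluster_size_p95": (float(np.percentile(cluster_sizes, 95))
                             if cluster_sizes.size else np.nan),
        "fraction_in_clusters": float(cluster_sizes.sum() / total_pos),
    }


def separation_index(patterns: Sequence[LabeledSpinePattern]) -> pd.DataFrame:
    """Separation Index for every dendrite, with slice-level expectation.

    f (per slice) = Σ positives / Σ spines over the slice's dendrites;
    p* = f × T per dendrite; SI = |p − p*| / p*. Slices with f = 0 yield
    NaN SI (logged): the expectation is degenerate there.
    """
    rows = []
    by_slice: dict[str, list[LabeledSpinePattern]] = {}
    for pat in patterns:
        by_slice.setdefault(pat.slice_id, []).append(pat)
    for slice_id, pats in sorted(by_slice.items()):
        total_p = sum(p.p for p in pats)
        total_T = sum(p.T for p in pats)
        f = total_p / total_T if total_T else 0.0
        if f == 0.0:
            logger.info("slice %s: f = 0, SI undefined", slice_id)
        for pat in pats:
            p_star = f * pat.T
            si = abs(pat.p - p_star) / p_star if p_star > 0 else np.nan
            rows.append(dict(slice_id=slice_id, dendrite_id=pat.dendrite_id,
                             region=pat.region, condition=pat.condition,
                             p=pat.p, T=pat.T, f=f, p_star=p_star, si=si))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline: simulate -> analyze -> report
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: GeneratorConfig, out_dir: str | Path,
                 with_intensity: bool = True) -> dict[str, str]:
    """Generate and write a synthetic dataset; echo the config alongside.

    Writes ``spines.csv`` (and ``intensity.csv`` unless disabled) plus
    ``generator_config.yaml``; returns the file manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, _ = generate_dataset(config)
    spine_path = out / "spines.csv"
    table.to_csv(spine_path, index=False, float_format="%.6f")
    manifest = {"spines": str(spine_path)}
    if with_intensity and not table.empty:
        intensity = generate_intensity_table(table, config)
        ipath = out / "intensity.csv"
        intensity.to_csv(ipath, index=False, float_format="%.6f")
        manifest["intensity"] = str(ipath)
    with open(out / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest["config"] = str(out / "generator_config.yaml")
    logger.info("simulated %d spines on %d dendrites -> %s",
                len(table), table["dendrite_id"].nunique() if len(table) else 0,
                spine_path)
    return manifest


def _analyze_intensity(path: Path, out: Path) -> str:
    """Per-spine intensity metrics table (EI, PSD enrichment, docked class)."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        rec = SpineIntensityRecord(
            spine_id=str(r["spine_id"]), channel=str(r.get("channel", "cherry")),
            spine_region_mean=r["spine_region_mean"],
            shaft_region_mean=r["shaft_region_mean"],
            background=r["background"], dendrite_mean=r["dendrite_mean"],
            psd_center=np.array([r["psd_x"], r["psd_y"], r["psd_z"]]),
            psd_radius=r["psd_radius"],
            peak_location=np.array([r["peak_x"], r["peak_y"], r["peak_z"]]),
            psd_integrated=r["psd_integrated"],
            filler_integrated=r["filler_integrated"],
            expressing=bool(r["expressing"]))
        row = {"spine_id": rec.spine_id, "expressing": int(rec.expressing)}
        try:
            row["ei"] = enrichment_index(rec) if rec.expressing else np.nan
        except ValueError as exc:
            logger.info("EI excluded: %s", exc)
            row["ei"] = np.nan
        row["psd_enrichment"] = homer_or_sep_enrichment(rec)
        row["docked_class"] = classify_docked(rec).value
        rows.append(row)
    out_path = out / "intensity_metrics.tsv"
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False,
                              float_format="%.6f")
    return str(out_path)


def run_analyze(config: RunConfig) -> dict:
    """Run every enabled statistic on a spine table; write tidy outputs.

    Consumes the CSV dialect written by :func:`run_simulate` (or any table
    with the same header). Writes one TSV per statistic plus a JSON run
    summary with counts, exclusions, seeds and a sha256 manifest of the
    data outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict[str, str] = {}
    t0 = time.perf_counter()

    if config.spine_table is None:
        gen = dataclasses.replace(config.generator, rng_seed=config.seed)
        sim_manifest = run_simulate(gen, out, with_intensity=config.intensity)
        spine_path = Path(sim_manifest["spines"])
        intensity_path = Path(sim_manifest["intensity"]) \
            if "intensity" in sim_manifest else None
        manifest.update(sim_manifest)
    else:
        spine_path = Path(config.spine_table)
        intensity_path = (Path(config.intensity_table)
                          if config.intensity_table else None)
    timings["simulate"] = time.perf_counter() - t0

    try:
        table = pd.read_csv(spine_path)
    except Exception as exc:
        raise ValueError(f"malformed spine table {spine_path}: {exc}") from exc
    patterns = patterns_from_table(table) if len(table) else []
    if not patterns:
        logger.warning("empty dendrite set: writing empty outputs")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if config.distances:
        t = time.perf_counter()
        rows = []
        for pat in patterns:
            if pat.p < 1 or pat.T < 2:
                continue
            obs = first_neighbor_distances(pat)
            for k in range(obs.spine_index.size):
                rows.append(dict(dendrite_id=pat.dendrite_id,
                                 region=pat.region, condition=pat.condition,
                                 source="observed", shuffle=-1,
                                 d_pp=obs.d_pp[k], d_pn=obs.d_pn[k]))
            null = shuffle_null(pat, config.n_shuffles, rng)
            for s_i, res in enumerate(null.results):
                for k in range(res.spine_index.size):
                    rows.append(dict(dendrite_id=pat.dendrite_id,
                                     region=pat.region, condition=pat.condition,
                                     source="shuffled", shuffle=s_i,
                                     d_pp=res.d_pp[k], d_pn=res.d_pn[k]))
        path = out / "neighbor_distances.tsv"
        pd.DataFrame(rows, columns=["dendrite_id", "region", "condition",
                                    "source", "shuffle", "d_pp", "d_pn"]
                     ).to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest["neighbor_distances"] = str(path)
        timings["distances"] = time.perf_counter() - t

    exclusions: list[dict] = []
    if config.probability:
        t = time.perf_counter()
        retained, exclusions = apply_exclusions(
            patterns, n_positions=config.n_positions)
        rows = []
        for pat in retained:
            curve = neighbor_probability_curve(pat, config.n_positions,
                                               config.rank_mode)
            for i in range(config.n_positions):
                rows.append(dict(dendrite_id=pat.dendrite_id,
                                 region=pat.region, condition=pat.condition,
                                 position=i + 1,
                                 probability=curve.probability[i],
                                 expected=curve.expected,
                                 increase=curve.increase[i],
                                 n_focal=curve.n_focal))
        path = out / "probability_curves.tsv"
        pd.DataFrame(rows, columns=["dendrite_id", "region", "condition",
                                    "position", "probability", "expected",
                                    "increase", "n_focal"]
                     ).to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest["probability_curves"] = str(path)
        timings["probability"] = time.perf_counter() - t

    if config.clusters:
        t = time.perf_counter()
        rows = []
        for pat in patterns:
            if pat.p < 1:
                continue
            asg = cluster_single_linkage(pat, config.cutoff_um)
            for uid, size in enumerate(asg.unit_sizes):
                rows.append(dict(dendrite_id=pat.dendrite_id,
                                 region=pat.region, condition=pat.condition,
                                 unit_id=uid, size=int(size),
                                 is_cluster=int(size >= 2)))
        path = out / "cluster_units.tsv"
        pd.DataFrame(rows, columns=["dendrite_id", "region", "condition",
                                    "unit_id", "size", "is_cluster"]
                     ).to_csv(path, sep="\t", index=False)
        manifest["cluster_units"] = str(path)
        timings["clusters"] = time.perf_counter() - t

    if config.separation:
        t = time.perf_counter()
        si = separation_index(patterns) if patterns else pd.DataFrame(
            columns=["slice_id", "dendrite_id", "region", "condition",
                     "p", "T", "f", "p_star", "si"])
        path = out / "separation_index.tsv"
        si.to_csv(path, sep="\t", index=False, float_format="%.6f")
        manifest["separation_index"] = str(path)
        timings["separation"] = time.perf_counter() - t

    if config.intensity and intensity_path is not None and intensity_path.exists():
        t = time.perf_counter()
        manifest["intensity_metrics"] = _analyze_intensity(intensity_path, out)
        timings["intensity"] = time.perf_counter() - t

    summary = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_dendrites": len(patterns),
        "n_spines": int(len(table)),
        "per_dendrite": [{"dendrite_id": p.dendrite_id, "T": p.T, "p": p.p}
                         for p in patterns],
        "exclusions": exclusions,
        "outputs": {k: _sha256(Path(v)) for k, v in sorted(manifest.items())},
        "wall_clock_s": {k: round(v, 4) for k, v in timings.items()},
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("analysis complete: %d dendrites, %d exclusions -> %s",
                len(patterns), len(exclusions), out)
    return summary


def _sem(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan


def run_report(run_dir: str | Path) -> str:
    """Render a markdown summary of a completed run's statistic tables.

    Per region × condition: positive-spine fractions, observed vs shuffled
    d_PP (mean ± SEM), the probability-increase table with the z-test
    against 1, spine-unit statistics, and the SI distribution summary.
    Sections whose stage outputs are missing are omitted (disabled stages)
    but a missing summary is an error.
    """
    run = Path(run_dir)
    summary_path = run / "run_summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"no run summary at {summary_path}; run the analyze stage first")
    with open(summary_path) as fh:
        summary = json.load(fh)

    lines = ["# Spine map analysis report", "",
             f"Dendrites: {summary['n_dendrites']}; "
             f"spines: {summary['n_spines']}; seed: {summary['seed']}", ""]
    counts = pd.DataFrame(summary["per_dendrite"])

    si_path = run / "separation_index.tsv"
    nd_path = run / "neighbor_distances.tsv"
    pc_path = run / "probability_curves.tsv"
    cu_path = run / "cluster_units.tsv"

    if si_path.exists():
        si = pd.read_csv(si_path, sep="\t")
        if len(si):
            lines += ["## Positive-spine fractions and Separation Index", ""]
            g = si.groupby(["region", "condition"]).agg(
                n_dendrites=("dendrite_id", "size"),
                positive_fraction=("f", "mean"),
                si_mean=("si", "mean"), si_median=("si", "median"))
            lines += [g.round(4).to_markdown(), ""]

    if nd_path.exists():
        nd = pd.read_csv(nd_path, sep="\t")
        if len(nd):
            lines += ["## First-neighbor distances (μm)", ""]
            g = nd.groupby(["region", "condition", "source"])["d_pp"].agg(
                mean="mean", sem=_sem, n="count")
            lines += [g.round(4).to_markdown(), ""]

    if pc_path.exists():
        pc = pd.read_csv(pc_path, sep="\t")
        if len(pc):
            lines += ["## Probability increase by neighbor position", "",
                      "Increase = probability / [(p−1)/(T−1)]; z-test vs 1.", ""]
            rows = []
            for (reg, cond, pos), g in pc.groupby(
                    ["region", "condition", "position"]):
                vals = g["increase"].to_numpy()
                try:
                    z, pval = ztest_vs_one(vals)
                except ValueError:
                    z, pval = np.nan, np.nan
                rows.append(dict(region=reg, condition=cond, position=pos,
                                 mean_increase=vals.mean(), sem=_sem(vals),
                                 z=z, p_value=pval))
            rep = pd.DataFrame(rows)
            rep = rep[rep["position"] <= 5]   # head of the curve; full data in TSV
            lines += [rep.round(4).to_markdown(index=False), ""]

    if cu_path.exists():
        cu = pd.read_csv(cu_path, sep="\t")
        if len(cu):
            lines += ["## Spine units (single-linkage, strict < cutoff)", ""]
            rows = []
            for (reg, cond), g in cu.groupby(["region", "condition"]):
                sizes = g["size"].to_numpy()
                clusters = sizes[sizes >= 2]
                rows.append(dict(
                    region=reg, condition=cond, n_units=len(sizes),
                    mean_unit_size=sizes.mean(),
                    fraction_in_clusters=clusters.sum() / sizes.sum(),
                    cluster_p5=np.percentile(clusters, 5) if clusters.size else np.nan,
                    cluster_p95=np.percentile(clusters, 95) if clusters.size else np.nan))
            lines += [pd.DataFrame(rows).round(4).to_markdown(index=False), ""]

    if summary["exclusions"]:
        lines += ["## Exclusions", ""]
        lines += [f"- {e['dendrite_id']}: rule ({e['rule']}) — {e['reason']}"
                  for e in summary["exclusions"]]
        lines += [""]
    if len(counts):
        lines += [f"Median spines/dendrite: {counts['T'].median():.0f}; "
                  f"median positives: {counts['p'].median():.0f}", ""]

    report = "\n".join(lines)
    (run / "report.md").write_text(report)
    logger.info("report written -> %s", run / "report.md")
    return report
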