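"""Marked point-pattern statistics on tissue-microarray cores.

The central quantity is the bivariate (cross-type) Ripley K function

    K_ij(d) = E[number of type-j cells within distance d of a typical
              type-i cell] / lambda_j,

estimated on a bounded observation window (a TMA core) as

    K_hat_ij(d) = |W| / (n_i * n_j) * sum over ordered pairs (x_i, x_j)
                  of e(x_i, x_j) * 1[dist(x_i, x_j) <= d],

where e is an edge-correction weight (identically 1 for correction
"none"; the reciprocal translation overlap |W| / |W ∩ W_{x_j - x_i}| for
correction "translation").  Under independence of the two types the
theoretical value is pi * d**2, and departures are judged against
pointwise Monte Carlo envelopes simulated from an independence null,
optionally aggregated family-wise across cores by taking per-distance
minima of the lower bounds and maxima of the upper bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely import affinity
from shapely.geometry import Point, Polygon

from .exceptions import EstimationError, ParameterError

__all__ = [
    "Window",
    "DiscWindow",
    "PolygonWindow",
    "MaskWindow",
    "MarkedPointPattern",
    "CrossKEstimate",
    "EnvelopeBand",
    "FamilyEnvelope",
    "default_distance_grid",
    "density",
    "cross_k",
    "envelope",
    "filter_cores",
    "family_envelope",
    "classify_association",
]


# ---------------------------------------------------------------------------
# Observation windows


class Window:
    """Abstract observation window in µm coordinates."""

    @property
    def area(self) -> float:
        raise NotImplementedError

    @property
    def diameter(self) -> float:
        raise NotImplementedError

    def contains(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def translation_weights(self, separations: np.ndarray) -> np.ndarray:
        """Edge-correction weights |W| / |W ∩ W_shifted| per pair separation.

        ``separations`` has shape (..., 2).
        """
        raise NotImplementedError


@dataclass(frozen=True)
class DiscWindow(Window):
    """Circular core window (the natural geometry of a TMA core)."""

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 350.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("disc radius must be positive")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d2 = (pts[..., 0] - self.center[0]) ** 2 + (pts[..., 1] - self.center[1]) ** 2
        return d2 <= self.radius**2 * (1 + 1e-12)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius * np.sqrt(rng.uniform(size=n))
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        return np.column_stack(
            [self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta)]
        )

    def translation_weights(self, separations: np.ndarray) -> np.ndarray:
        # Overlap of two equal discs at centre distance t (lens area).
        t = np.linalg.norm(np.asarray(separations, dtype=float), axis=-1)
        R = self.radius
        t = np.clip(t, 0.0, 2.0 * R * (1 - 1e-15))
        lens = 2.0 * R**2 * np.arccos(t / (2.0 * R)) - (t / 2.0) * np.sqrt(
            4.0 * R**2 - t**2
        )
        return self.area / lens


@dataclass(frozen=True)
class PolygonWindow(Window):
    """Simple-polygon window (e.g. an annotated tissue region)."""

    polygon: Polygon

    def __post_init__(self):
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ParameterError("window polygon must be simple and non-empty")
        if self.polygon.area <= 0:
            raise ParameterError("window polygon must have positive area")

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def diameter(self) -> float:
        xy = np.asarray(self.polygon.exterior.coords)
        return float(cdist(xy, xy).max())

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        buffered = self.polygon.buffer(1e-9)
        return np.array([buffered.covers(Point(*p)) for p in pts.reshape(-1, 2)]).reshape(
            pts.shape[:-1]
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        minx, miny, maxx, maxy = self.polygon.bounds
        out: list[np.ndarray] = []
        need = n
        while need > 0:
            cand = np.column_stack(
                [rng.uniform(minx, maxx, size=2 * need + 16),
                 rng.uniform(miny, maxy, size=2 * need + 16)]
            )
            keep = cand[self.contains(cand)]
            out.append(keep[:need])
            need -= len(keep[:need])
        return np.concatenate(out)[:n]

    def translation_weights(self, separations: np.ndarray) -> np.ndarray:
        seps = np.asarray(separations, dtype=float).reshape(-1, 2)
        w = np.empty(len(seps))
        for k, (dx, dy) in enumerate(seps):
            shifted = affinity.translate(self.polygon, xoff=dx, yoff=dy)
            overlap = self.polygon.intersection(shifted).area
            w[k] = self.area / overlap if overlap > 0 else np.inf
        return w.reshape(np.asarray(separations).shape[:-1])


@dataclass(frozen=True)
class MaskWindow(Window):
    """Raster mask window: boolean grid of pixels covering a compartment.

    Used for compartment-restricted analyses where the region is an
    irregular tissue compartment rather than the whole core.  The
    translation correction is not defined on rasters here; use
    correction "none" for mask windows.
    """

    mask: np.ndarray  # boolean, shape (ny, nx)
    origin: tuple[float, float]  # (x, y) of the lower-left pixel corner
    pixel: float  # pixel side length, µm

    def __post_init__(self):
        if self.pixel <= 0:
            raise ParameterError("pixel size must be positive")
        if not np.asarray(self.mask).any():
            raise ParameterError("mask window has zero area")

    @property
    def area(self) -> float:
        return float(np.count_nonzero(self.mask)) * self.pixel**2

    @property
    def diameter(self) -> float:
        ys, xs = np.nonzero(self.mask)
        pts = np.column_stack(
            [self.origin[0] + (xs + 0.5) * self.pixel,
             self.origin[1] + (ys + 0.5) * self.pixel]
        )
        hull_ids = np.unique(
            np.concatenate([pts.argmin(axis=0), pts.argmax(axis=0)])
        )
        # cheap bound refined over the full set only if the mask is small
        if len(pts) <= 2048:
            return float(cdist(pts, pts).max()) + self.pixel * math.sqrt(2)
        sub = pts[hull_ids]
        return float(cdist(sub, sub).max()) + self.pixel * math.sqrt(2)

    def _indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.asarray(points, dtype=float)
        ix = np.floor((pts[..., 0] - self.origin[0]) / self.pixel).astype(int)
        iy = np.floor((pts[..., 1] - self.origin[1]) / self.pixel).astype(int)
        return iy, ix

    def contains(self, points: np.ndarray) -> np.ndarray:
        iy, ix = self._indices(points)
        ny, nx = self.mask.shape
        inside = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        out = np.zeros(inside.shape, dtype=bool)
        out[inside] = np.asarray(self.mask)[iy[inside], ix[inside]]
        return out

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        ys, xs = np.nonzero(self.mask)
        pick = rng.integers(0, len(xs), size=n)
        jitter = rng.uniform(0.0, self.pixel, size=(n, 2))
        return np.column_stack(
            [self.origin[0] + xs[pick] * self.pixel + jitter[:, 0],
             self.origin[1] + ys[pick] * self.pixel + jitter[:, 1]]
        )

    def translation_weights(self, separations: np.ndarray) -> np.ndarray:
        raise ParameterError(
            "translation correction is not available for mask windows; "
            "use correction='none'"
        )


# ---------------------------------------------------------------------------
# Marked point pattern


@dataclass
class MarkedPointPattern:
    """Cell locations with phenotype marks inside a core window.

    points       (n, 2) float array of (x, y) in µm
    marks        length-n phenotype labels (e.g. "CD8", "CAIX", "other")
    window       observation window
    compartments optional length-n labels in {"tumor", "stroma"}
    compartment_areas  areal µm² per compartment label (from a mask)
    compartment_windows  optional per-compartment Window objects
    """

    points: np.ndarray
    marks: np.ndarray
    window: Window
    compartments: np.ndarray | None = None
    core_id: str = "core"
    tma_id: str = "A"
    compartment_areas: Mapping[str, float] | None = None
    compartment_windows: Mapping[str, Window] | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.marks = np.asarray(self.marks, dtype=object)
        if len(self.marks) != len(self.points):
            raise ParameterError("marks and points must have equal length")
        if self.compartments is not None:
            self.compartments = np.asarray(self.compartments, dtype=object)
            if len(self.compartments) != len(self.points):
                raise ParameterError("compartments and points must have equal length")
        if len(self.points) and not self.window.contains(self.points).all():
            raise ParameterError("all points must lie inside the window")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def count(self, mark: str, compartment: str | None = None) -> int:
        sel = self.marks == mark
        if compartment is not None:
            if self.compartments is None:
                raise ParameterError("pattern has no compartment labels")
            sel &= self.compartments == compartment
        return int(np.count_nonzero(sel))

    def points_of(self, mark: str, compartment: str | None = None) -> np.ndarray:
        sel = self.marks == mark
        if compartment is not None:
            if self.compartments is None:
                raise ParameterError("pattern has no compartment labels")
            sel &= self.compartments == compartment
        return self.points[sel]

    def subset_compartment(self, compartment: str) -> "MarkedPointPattern":
        """Restrict points *and* window to one tissue compartment."""
        if self.compartments is None:
            raise ParameterError("pattern has no compartment labels")
        sel = self.compartments == compartment
        if self.compartment_windows and compartment in self.compartment_windows:
            win: Window = self.compartment_windows[compartment]
        else:
            raise ParameterError(
                f"no window geometry available for compartment {compartment!r}"
            )
        return MarkedPointPattern(
            points=self.points[sel],
            marks=self.marks[sel],
            window=win,
            compartments=self.compartments[sel],
            core_id=self.core_id,
            tma_id=self.tma_id,
        )


# ---------------------------------------------------------------------------
# Densities


def density(
    pattern: MarkedPointPattern,
    mark: str,
    compartment: str | None = None,
) -> float:
    """Cell density (cells/µm²): matching count over the relevant area.

    Overall density divides by the window area; compartmental density by
    that compartment's mask area.
    """
    if compartment is None:
        area = pattern.window.area
    else:
        areas = pattern.compartment_areas or {}
        area = float(areas.get(compartment, 0.0))
        if area <= 0:
            raise EstimationError(
                f"compartment {compartment!r} has zero or unknown area; "
                "density is undefined"
            )
    return pattern.count(mark, compartment) / area


# ---------------------------------------------------------------------------
# Cross-K estimation


def default_distance_grid(d_max: float = 200.0, step: float = 2.0) -> np.ndarray:
    """Default distance grid: 0 to ``d_max`` µm in ``step`` µm increments."""
    return np.arange(0.0, d_max + step / 2, step)


@dataclass(frozen=True)
class CrossKEstimate:
    """Estimated cross-type K function on a distance grid."""

    distances: np.ndarray
    k_hat: np.ndarray
    lambda_i: float
    lambda_j: float
    n_i: int
    n_j: int
    correction: str
    window_area: float
    core_id: str = "core"
    tma_id: str = "A"

    @property
    def k_theo(self) -> np.ndarray:
        """Independence benchmark pi*d**2."""
        return math.pi * self.distances**2


def _check_distances(distances: np.ndarray, window: Window) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ParameterError("distances must be a non-empty 1-d grid")
    if np.any(np.diff(d) <= 0):
        raise ParameterError("distances must be strictly increasing")
    if d[0] < 0:
        raise ParameterError("distances must be nonnegative")
    if d[-1] > window.diameter * (1 + 1e-9):
        raise ParameterError(
            f"max distance {d[-1]:g} exceeds window diameter {window.diameter:g}"
        )
    return d


def _pair_weights(
    window: Window, pts_i: np.ndarray, pts_j: np.ndarray, correction: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise distances and edge weights for ordered (i, j) pairs."""
    t = cdist(pts_i, pts_j)
    if correction == "none":
        w = np.ones_like(t)
    elif correction == "translation":
        seps = pts_j[None, :, :] - pts_i[:, None, :]
        w = window.translation_weights(seps)
    else:
        raise ParameterError(f"unknown edge correction {correction!r}")
    return t, w


def _accumulate_khat(
    t: np.ndarray,
    w: np.ndarray,
    distances: np.ndarray,
    scale: float,
) -> np.ndarray:
    """K_hat per grid distance from pair distances/weights.

    Pairs at distance exactly 0 (duplicate coordinates) count for every
    d > 0 but not at d = 0, so that K_hat(0) = 0.
    """
    tf = t.ravel()
    wf = w.ravel()
    idx = np.searchsorted(distances, tf, side="left")
    zero = tf == 0.0
    if zero.any():
        idx[zero] = np.searchsorted(distances, 0.0, side="right")
    keep = idx < len(distances)
    binned = np.bincount(idx[keep], weights=wf[keep], minlength=len(distances))
    return scale * np.cumsum(binned)


def cross_k(
    pattern: MarkedPointPattern,
    type_i: str = "CD8",
    type_j: str = "CAIX",
    distances: np.ndarray | None = None,
    correction: Literal["none", "translation"] = "translation",
) -> CrossKEstimate:
    """Estimate the cross-K function between two phenotypes on one core."""
    win = pattern.window
    if distances is None:
        distances = default_distance_grid(min(200.0, win.diameter / 2))
    d = _check_distances(distances, win)
    pts_i = pattern.points_of(type_i)
    pts_j = pattern.points_of(type_j)
    for name, pts in ((type_i, pts_i), (type_j, pts_j)):
        if len(pts) == 0:
            raise EstimationError(f"no points of type {name!r}; cross-K undefined")
    t, w = _pair_weights(win, pts_i, pts_j, correction)
    scale = win.area / (len(pts_i) * len(pts_j))
    k_hat = _accumulate_khat(t, w, d, scale)
    return CrossKEstimate(
        distances=d,
        k_hat=k_hat,
        lambda_i=len(pts_i) / win.area,
        lambda_j=len(pts_j) / win.area,
        n_i=len(pts_i),
        n_j=len(pts_j),
        correction=correction,
        window_area=win.area,
        core_id=pattern.core_id,
        tma_id=pattern.tma_id,
    )


# ---------------------------------------------------------------------------
# Monte Carlo envelopes


@dataclass(frozen=True)
class EnvelopeBand:
    """Pointwise Monte Carlo envelope for a cross-K estimate."""

    distances: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    n_sim: int
    null_model: str
    correction: str
    k_obs: np.ndarray | None = None
    core_id: str = "core"
    tma_id: str = "A"


def envelope(
    pattern: MarkedPointPattern,
    type_i: str = "CD8",
    type_j: str = "CAIX",
    distances: np.ndarray | None = None,
    n_sim: int = 199,
    level: float = 0.99,
    null_model: Literal["random_labeling", "csr_j"] = "random_labeling",
    correction: Literal["none", "translation"] = "translation",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnvelopeBand:
    """Pointwise min/max envelope of cross-K under an independence null.

    ``random_labeling`` permutes the type_i/type_j marks over their fixed
    union of locations (tests mark independence given the observed
    spatial arrangement).  ``csr_j`` holds type_i fixed and re-simulates
    type_j as CSR with the same count (tests independence against a
    homogeneous type_j).  A pointwise min/max band over ``n_sim``
    simulations has two-sided exceedance probability 2/(n_sim+1) under
    the null, so n_sim must satisfy 2/(n_sim+1) <= 1 - level.
    """
    if not 0 < level < 1:
        raise ParameterError("level must lie in (0, 1)")
    if 2.0 / (n_sim + 1) > (1.0 - level) * (1 + 1e-12):
        raise ParameterError(
            f"n_sim={n_sim} cannot attain a {level:.0%} pointwise min/max band; "
            f"need 2/(n_sim+1) <= {1 - level:g}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    win = pattern.window
    if distances is None:
        distances = default_distance_grid(min(200.0, win.diameter / 2))
    d = _check_distances(distances, win)

    obs = cross_k(pattern, type_i, type_j, d, correction)
    n_i, n_j = obs.n_i, obs.n_j

    sims = np.empty((n_sim, len(d)))
    if null_model == "random_labeling":
        sel = (pattern.marks == type_i) | (pattern.marks == type_j)
        pts = pattern.points[sel]
        m = len(pts)
        # positions are fixed: compute pair distances/weights once
        t, w = _pair_weights(win, pts, pts, correction)
        np.fill_diagonal(t, np.inf)  # exclude self-pairs
        idx_all = np.searchsorted(d, t, side="left")
        zero = t == 0.0
        if zero.any():
            idx_all[zero] = np.searchsorted(d, 0.0, side="right")
        scale = win.area / (n_i * n_j)
        labels = np.zeros(m, dtype=bool)  # True = type_i
        labels[:n_i] = True
        for s in range(n_sim):
            perm = rng.permutation(m)
            li = labels[perm]
            sub_idx = idx_all[np.ix_(li, ~li)].ravel()
            sub_w = w[np.ix_(li, ~li)].ravel()
            keep = sub_idx < len(d)
            binned = np.bincount(
                sub_idx[keep], weights=sub_w[keep], minlength=len(d)
            )
            sims[s] = scale * np.cumsum(binned)
    elif null_model == "csr_j":
        pts_i = pattern.points_of(type_i)
        scale = win.area / (n_i * n_j)
        for s in range(n_sim):
            pts_j = win.sample_uniform(n_j, rng)
            t, w = _pair_weights(win, pts_i, pts_j, correction)
            sims[s] = _accumulate_khat(t, w, d, scale)
    else:
        raise ParameterError(f"unknown null model {null_model!r}")

    return EnvelopeBand(
        distances=d,
        lo=sims.min(axis=0),
        hi=sims.max(axis=0),
        level=level,
        n_sim=n_sim,
        null_model=null_model,
        correction=correction,
        k_obs=obs.k_hat,
        core_id=pattern.core_id,
        tma_id=pattern.tma_id,
    )


# ---------------------------------------------------------------------------
# Core filtering (sparse cores give unstable envelopes)


@dataclass(frozen=True)
class FilterResult:
    kept: list
    kept_ids: list
    dropped: dict  # id -> reason string
    threshold: float


def filter_cores(
    patterns: Iterable[MarkedPointPattern],
    threshold: float = 4e-5,
    type_i: str = "CD8",
    type_j: str = "CAIX",
    mode: Literal["combined", "per_type"] = "combined",
    compartment: str | None = None,
) -> FilterResult:
    """Keep cores whose marked-cell density strictly exceeds ``threshold``.

    The default 4e-5 cells/µm² mirrors the evaluability rule used for
    envelope stability; "combined" pools both marked types, "per_type"
    requires each type separately to exceed the threshold.
    """
    if threshold < 0:
        raise ParameterError("threshold must be nonnegative")
    kept, kept_ids, dropped = [], [], {}
    for p in patterns:
        key = (p.tma_id, p.core_id)
        if compartment is None:
            area = p.window.area
        else:
            area = float((p.compartment_areas or {}).get(compartment, 0.0))
            if area <= 0:
                dropped[key] = f"compartment {compartment!r} has zero area"
                continue
        c_i = p.count(type_i, compartment)
        c_j = p.count(type_j, compartment)
        if mode == "combined":
            dens = (c_i + c_j) / area
            ok = dens > threshold
            reason = f"combined density {dens:.3g} <= threshold {threshold:g}"
        elif mode == "per_type":
            d_i, d_j = c_i / area, c_j / area
            ok = d_i > threshold and d_j > threshold
            reason = (
                f"per-type density ({d_i:.3g}, {d_j:.3g}) "
                f"not both > threshold {threshold:g}"
            )
        else:
            raise ParameterError(f"unknown filter mode {mode!r}")
        if ok:
            kept.append(p)
            kept_ids.append(key)
        else:
            dropped[key] = reason
    return FilterResult(kept=kept, kept_ids=kept_ids, dropped=dropped, threshold=threshold)


# ---------------------------------------------------------------------------
# Family-wise aggregation and classification


@dataclass(frozen=True)
class FamilyEnvelope:
    """Per-distance min of lower and max of upper bounds across cores."""

    distances: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    core_ids: list


def family_envelope(bands: Sequence[EnvelopeBand]) -> FamilyEnvelope:
    """Aggregate per-core envelopes by pointwise min/max over cores."""
    bands = list(bands)
    if not bands:
        raise ParameterError("family envelope needs at least one band")
    d0 = bands[0].distances
    for b in bands[1:]:
        if len(b.distances) != len(d0) or not np.array_equal(b.distances, d0):
            raise ParameterError(
                "envelope distance grids differ; aggregate on a common grid"
            )
    lo = np.min([b.lo for b in bands], axis=0)
    hi = np.max([b.hi for b in bands], axis=0)
    return FamilyEnvelope(
        distances=d0,
        lo=lo,
        hi=hi,
        core_ids=[(b.tma_id, b.core_id) for b in bands],
    )


@dataclass(frozen=True)
class AssociationClassification:
    distances: np.ndarray
    labels: np.ndarray  # "below" | "within" | "above" per distance
    summary: str
    d_range: tuple[float, float]


def classify_association(
    estimate: CrossKEstimate,
    band: EnvelopeBand | FamilyEnvelope,
    d_range: tuple[float, float] | None = None,
) -> AssociationClassification:
    """Label the estimate against the band per distance and summarize.

    "below" indicates repulsion-like (immune-excluded) spatial
    association, "above" attraction-like co-occurrence.  The summary is
    the label of the longest contiguous run within ``d_range``.
    """
    if len(estimate.distances) != len(band.distances) or not np.array_equal(
        estimate.distances, band.distances
    ):
        raise ParameterError("estimate and band are on different distance grids")
    labels = np.where(
        estimate.k_hat < band.lo,
        "below",
        np.where(estimate.k_hat > band.hi, "above", "within"),
    ).astype(object)
    d = estimate.distances
    if d_range is None:
        d_range = (float(d[0]), float(d[-1]))
    sel = (d >= d_range[0]) & (d <= d_range[1])
    lab_sel = labels[sel]
    if len(lab_sel) == 0:
        raise ParameterError("d_range contains no grid distances")
    best_label, best_len = str(lab_sel[0]), 0
    run_label, run_len = None, 0
    for lab in lab_sel:
        if lab == run_label:
            run_len += 1
        else:
            run_label, run_len = lab, 1
        if run_len > best_len:
            best_label, best_len = str(run_label), run_len
    return AssociationClassification(
        distances=d, labels=labels, summary=best_label, d_range=d_range
    )
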