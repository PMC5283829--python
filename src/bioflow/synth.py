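"""Synthetic inputs with known ground truth for the whole pipeline.

Every input the analysis consumes can be generated here with region-level
ground truth attached: two-channel chamber scenes (dark obstacle disks,
Gaussian biofilm blobs per strain, Poisson-Gaussian camera noise),
bead-streak stacks whose streaks run only through open flow corridors,
competition tables drawn from an explicit selection function, and logistic
OD600 growth curves.  Clogging is emulated by growing a connected blocked
set of regions from a random seed site, matching the observation that
mutant accumulation follows localized upstream obstruction.

All randomness flows through one integer seed per call; outputs are
bit-reproducible.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.draw import line_aa

from .chamber import ChamberLayout
from .regions import ColumnSet, Tessellation, columns_from_layout, tessellate

__all__ = [
    "GroundTruth",
    "SelectionModel",
    "CompetitionRecord",
    "SceneParams",
    "sample_region_truth",
    "sample_occurrence_calls",
    "render_chamber_scene",
    "render_bead_stack",
    "sample_competition",
    "sample_growth_curves",
]


@dataclass(frozen=True)
class GroundTruth:
    """Region-level truth for a synthetic scene.

    ``blocked`` marks regions whose local flow has been obstructed (grown as
    a connected cluster, i.e. a clog and its wake); ``wt``/``mutant`` mark
    regions truly occupied by each strain's biofilm clusters.
    """

    blocked: np.ndarray  # (m,) bool
    wt: np.ndarray  # (m,) bool
    mutant: np.ndarray  # (m,) bool

    @property
    def flow(self) -> np.ndarray:
        return np.where(self.blocked, "blocked", "open").astype(object)

    @property
    def n_regions(self) -> int:
        return len(self.blocked)


@dataclass(frozen=True)
class SelectionModel:
    """Parametric selection regime for competition outcomes.

    ``uniform_positive``:            Δf = a * f0 * (1 - f0)
    ``negative_freq_dependent``:     Δf = a * f0 * (1 - f0) * (f_c - f0)

    Both vanish at fixation (f0 = 0 or 1); the frequency-dependent form
    favours the wild type below the critical frequency f_c and the
    matrix-deficient mutant above it.  Gaussian noise of sd ``noise_sd`` is
    added to the final frequency, which is then clipped to [0, 1].
    """

    regime: str = "negative_freq_dependent"
    a: float = 1.0
    f_c: float = 0.6
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("uniform_positive", "negative_freq_dependent"):
            raise ValueError(f"unknown selection regime: {self.regime!r}")
        if self.a <= 0:
            raise ValueError("selection strength a must be positive")
        if not (0.0 < self.f_c < 1.0):
            raise ValueError("critical frequency f_c must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def delta_f(self, f0: np.ndarray) -> np.ndarray:
        f0 = np.asarray(f0, dtype=float)
        base = self.a * f0 * (1.0 - f0)
        if self.regime == "uniform_positive":
            return base
        return base * (self.f_c - f0)


@dataclass(frozen=True)
class CompetitionRecord:
    """One competition replicate: initial and final wild-type frequency."""

    condition: str
    f0: float
    f72: float

    @property
    def delta_f(self) -> float:
        return self.f72 - self.f0


@dataclass(frozen=True)
class SceneParams:
    """Rendering and truth parameters for a synthetic chamber scene.

    Intensities are 16-bit camera counts.  Default occupancy probabilities
    encode the study scenario: wild type settles independently of flow,
    while the matrix-deficient mutant is ~5x more likely (odds 5:1) to
    occupy a blocked region than an open one.
    """

    um_per_px: float = 8.0
    background: float = 300.0
    column_level: float = 5.0
    blob_snr: float = 8.0  # minimum blob peak over background noise sd
    blob_mean_elevation: float = 60.0  # target region-mean lift in an occupied region
    blobs_per_region: tuple[int, int] = (1, 4)
    read_noise_sd: float = 10.0
    noise: bool = True
    blocked_fraction: float = 0.4
    p_wt: float = 0.5
    p_mut_blocked: float = 0.75
    p_mut_open: float = 0.15


def _grow_blocked(
    m: int, n_blocked: int, adjacency: list[set[int]], rng: np.random.Generator
) -> np.ndarray:
    """Grow a connected blocked patch breadth-first from a random clog site."""
    blocked = np.zeros(m, dtype=bool)
    seed_region = int(rng.integers(m))
    frontier = [seed_region]
    blocked[seed_region] = True
    count = 1
    while frontier and count < n_blocked:
        current = frontier.pop(0)
        nbrs = [n for n in sorted(adjacency[current]) if not blocked[n]]
        rng.shuffle(nbrs)
        for nb in nbrs:
            if count >= n_blocked:
                break
            blocked[nb] = True
            frontier.append(nb)
            count += 1
    # The graph may be too fragmented to reach the target count; accept
    # what the connected growth produced.
    return blocked


def _open_spans(
    blocked: np.ndarray, adjacency: list[set[int]], x: np.ndarray, width: float
) -> bool:
    """Does a connected open corridor reach both inlet and outlet thirds?"""
    open_set = set(np.flatnonzero(~blocked).tolist())
    seen: set[int] = set()
    for start in open_set:
        if start in seen:
            continue
        comp = {start}
        todo = [start]
        while todo:
            node = todo.pop()
            for nb in adjacency[node]:
                if nb in open_set and nb not in comp:
                    comp.add(nb)
                    todo.append(nb)
        seen |= comp
        cx = x[list(comp)]
        if cx.min() <= width / 3.0 and cx.max() >= 2.0 * width / 3.0:
            return True
    return False


def sample_region_truth(
    n_regions: int,
    adjacency: list[set[int]] | None,
    params: SceneParams,
    rng: np.random.Generator,
    centroid_x: np.ndarray | None = None,
    width: float | None = None,
    max_tries: int = 20,
) -> GroundTruth:
    """Draw region-level flow and occupancy ground truth.

    The blocked set is grown breadth-first from one random clog site over
    the adjacency graph until ``blocked_fraction`` of regions are blocked,
    giving a connected clogged patch.  When region x-positions and the
    chamber width are supplied, clog sites are redrawn (up to
    ``max_tries``) until an open corridor still spans inlet to outlet, as
    in a partially — not fully — clogged chamber.  Without adjacency (pure
    statistical replicates) a random subset is blocked instead.  Occupancy
    is Bernoulli per region and channel with flow-class-dependent mutant
    probability.
    """
    m = int(n_regions)
    if m < 1:
        raise ValueError("need at least one region")
    n_blocked = int(round(params.blocked_fraction * m))
    blocked = np.zeros(m, dtype=bool)
    if n_blocked > 0:
        if adjacency is None:
            blocked[rng.choice(m, size=n_blocked, replace=False)] = True
        else:
            for _ in range(max_tries):
                blocked = _grow_blocked(m, n_blocked, adjacency, rng)
                if centroid_x is None or width is None:
                    break
                if _open_spans(blocked, adjacency, centroid_x, width):
                    break
    wt = rng.random(m) < params.p_wt
    p_mut = np.where(blocked, params.p_mut_blocked, params.p_mut_open)
    mutant = rng.random(m) < p_mut
    return GroundTruth(blocked=blocked, wt=wt, mutant=mutant)


def _add_blob(
    img: np.ndarray,
    mask: np.ndarray,
    cx: float,
    cy: float,
    sigma: float,
    flux: float,
    min_peak: float = 0.0,
) -> None:
    """Add a Gaussian spot clipped to ``mask``, carrying exactly ``flux`` counts.

    Clipping confines each biofilm cluster to its ground-truth region (and
    off obstacle disks), so region-level truth is exact by construction;
    renormalizing to the requested flux keeps the region-mean lift
    independent of how much of the kernel the mask cuts away.
    """
    h, w = img.shape
    half = int(4 * sigma) + 1
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    kernel = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2))
    kernel *= mask[y0:y1, x0:x1]
    total = kernel.sum()
    if total > 0:
        flux = max(flux, min_peak * total)  # honour the SNR floor on the peak
        img[y0:y1, x0:x1] += flux / total * kernel


def sample_occurrence_calls(
    n_regions: int,
    params: SceneParams,
    rng: np.random.Generator,
    mean_area_um2: float = 4.0e4,
    area_cv: float = 0.6,
) -> pd.DataFrame:
    """Region-call table for one statistical replicate, without imaging.

    Draws region truth (random blocked subset, Bernoulli occupancy) and
    log-normal effective areas, and reports the truth as the calls — the
    replicate-level ingredient for power and type-I studies of the
    co-occurrence tests at many repetitions, where rendering and
    re-segmenting images would add nothing but runtime.
    """
    truth = sample_region_truth(n_regions, None, params, rng)
    sigma = np.sqrt(np.log(1.0 + area_cv**2))
    areas = rng.lognormal(np.log(mean_area_um2) - sigma**2 / 2.0, sigma, size=n_regions)
    return pd.DataFrame(
        {
            "region_id": np.arange(n_regions),
            "flow": truth.flow,
            "wt_call": truth.wt,
            "mut_call": truth.mutant,
            "area_um2": areas,
        }
    )


def render_chamber_scene(
    layout: ChamberLayout,
    params: SceneParams | None = None,
    image_shape: tuple[int, int] | None = None,
    seed: int | None = None,
    truth: GroundTruth | None = None,
) -> tuple[np.ndarray, GroundTruth, Tessellation]:
    """Render a two-channel epifluorescence scene with region-level truth.

    Returns ``(image, truth, tess)`` where ``image`` has shape (2, H, W)
    (channel 0 = GFP/wild type, channel 1 = mCherry/mutant, uint16).
    Columns are near-zero disks on a fluorescent background; each
    truth-occupied region receives 1-4 Gaussian biofilm blobs confined to
    the region interior with peak SNR ``blob_snr`` over the background shot
    noise; Poisson-Gaussian noise is applied unless ``params.noise`` is
    False.
    """
    params = params or SceneParams()
    if layout.n_columns < 3:
        raise ValueError("layout must contain at least 3 columns")
    if params.um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    if image_shape is None:
        image_shape = (
            int(np.ceil(layout.height / params.um_per_px)),
            int(np.ceil(layout.width / params.um_per_px)),
        )
    h, w = image_shape
    cols_px = columns_from_layout(layout, params.um_per_px)
    if np.any(cols_px.columns[:, 0] + cols_px.columns[:, 2] > w) or np.any(
        cols_px.columns[:, 1] + cols_px.columns[:, 2] > h
    ):
        raise ValueError("image too small to contain the layout at this pixel size")
    tess = tessellate(cols_px, (h, w), um_per_px=params.um_per_px)
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = sample_region_truth(
            tess.n_regions,
            tess.adjacency(),
            params,
            rng,
            centroid_x=tess.centroids()[:, 0],
            width=float(w),
        )
    elif truth.n_regions != tess.n_regions:
        raise ValueError("supplied truth does not match the layout's tessellation")

    noise_sd = np.sqrt(params.background + params.read_noise_sd**2)
    channels = np.empty((2, h, w), dtype=float)
    for ch, occupied in enumerate((truth.wt, truth.mutant)):
        img = np.full((h, w), params.background, dtype=float)
        for region in np.flatnonzero(occupied):
            mask = tess.effective_mask(region)
            if not mask.any():
                continue
            edt = distance_transform_edt(mask)
            area = mask.sum()
            interior = np.argwhere(edt >= 0.5 * edt.max())
            n_blobs = int(rng.integers(params.blobs_per_region[0], params.blobs_per_region[1] + 1))
            # Split a fixed total flux (region-mean lift x area) across the
            # blobs so the occupied-region mean is well defined regardless
            # of how thin the region is; the kernel is clipped to the
            # region mask, so the lift per region is exact.
            flux = params.blob_mean_elevation * area
            for _ in range(n_blobs):
                cy, cx = interior[rng.integers(len(interior))]
                sigma = max(min(0.15 * np.sqrt(area), edt[cy, cx] / 2.0), 1.0)
                share = flux / n_blobs * rng.uniform(0.8, 1.2)
                _add_blob(
                    img, mask, cx, cy, sigma, share, min_peak=params.blob_snr * noise_sd
                )
        # Obstacles mask any signal: re-impose the dark disks last.
        img[tess.column_mask] = params.column_level
        if params.noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            img += rng.normal(0.0, params.read_noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0, 65535)
    return channels.astype(np.uint16), truth, tess


def render_bead_stack(
    tess: Tessellation,
    truth: GroundTruth,
    n_frames: int = 12,
    seed: int | None = None,
    streak_level: float = 3000.0,
    background: float = 50.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Render a stack of long-exposure bead-streak frames.

    Tracer beads advected by the flow appear as bright anti-aliased
    polylines joining centroids of adjacent *open* regions (adjacency =
    shared triangulation edge); blocked regions and obstacle disks receive
    no streak pixels.  Each of the ``n_frames`` frames carries an
    independent subset of the streak paths, as when integrating successive
    exposures.  The default frame count sits in the 10-15 range typical of
    such acquisitions.

    If no chain of open regions connects the inlet side (low x) to the
    outlet side (high x), a warning is emitted and the stack contains no
    streaks at all.
    """
    if truth.n_regions != tess.n_regions:
        raise ValueError("truth does not tessellate this layout")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    h, w = tess.label_image.shape
    stack = np.full((n_frames, h, w), background, dtype=float)

    open_idx = np.flatnonzero(~truth.blocked)
    adj = tess.adjacency()
    # Route streaks through each region's most-interior pixel: the vertex
    # centroid of a sliver triangle can fall inside an obstacle disk.
    cent = tess.interior_points()

    # Walks covering every open region: depth-first traversal (with
    # backtracking) of each open connected component, split into streaks of
    # >= 3 regions where the component allows.
    open_set = set(open_idx.tolist())
    seen: set[int] = set()
    walks: list[list[int]] = []
    components: list[set[int]] = []
    for start in open_idx:
        if start in seen:
            continue
        comp: set[int] = set()
        walk: list[int] = []
        visited: set[int] = set()

        def dfs(node: int) -> None:
            visited.add(node)
            comp.add(node)
            walk.append(node)
            nbrs = sorted(n for n in adj[node] if n in open_set and n not in visited)
            rng.shuffle(nbrs)
            for nb in nbrs:
                dfs(nb)
                walk.append(node)  # backtrack through this centroid

        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, tess.n_regions + 100))
        try:
            dfs(int(start))
        finally:
            sys.setrecursionlimit(old_limit)
        seen |= comp
        walks.append(walk)
        components.append(comp)

    # Inlet-outlet connectivity: flow (hence beads) requires an open path
    # spanning the chamber in the flow direction.
    spanning = False
    if len(open_idx):
        xs = cent[:, 0]
        for comp in components:
            comp_x = xs[list(comp)]
            # A corridor counts as spanning when it reaches both the inlet
            # and outlet thirds of the chamber width.
            if comp_x.min() <= w / 3.0 and comp_x.max() >= 2.0 * w / 3.0:
                spanning = True
                break
    if not spanning:
        warnings.warn("no open path spans inlet to outlet; rendering a streak-free stack")
        out = stack
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, size=out.shape)
        return np.clip(out, 0, 65535).astype(np.uint16)

    forbidden = tess.column_mask.copy()
    for region in np.flatnonzero(truth.blocked):
        forbidden |= tess.effective_mask(region)

    for walk in walks:
        if len(walk) == 1:
            # Isolated open region: a short streak through its centroid.
            x, y = cent[walk[0]]
            segs = [((x - 3, y), (x + 3, y))]
        else:
            segs = [
                (tuple(cent[walk[i]]), tuple(cent[walk[i + 1]]))
                for i in range(len(walk) - 1)
            ]
        # Chunk consecutive segments into streaks spanning >= 3 regions and
        # hand each streak to a random frame.
        chunk = max(2, 3 - 1)
        for i in range(0, len(segs), chunk):
            frame = int(rng.integers(n_frames))
            for (x0, y0), (x1, y1) in segs[i : i + chunk]:
                rr, cc, val = line_aa(
                    int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
                )
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rr, cc, val = rr[ok], cc[ok], val[ok]
                keep = ~forbidden[rr, cc]
                img = stack[frame]
                img[rr[keep], cc[keep]] = np.maximum(
                    img[rr[keep], cc[keep]], background + val[keep] * streak_level
                )
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return np.clip(stack, 0, 65535).astype(np.uint16)


def sample_competition(
    model: SelectionModel,
    f0_list,
    seed: int | None = None,
    condition: str = "columns",
) -> list[CompetitionRecord]:
    """Draw competition outcomes f0 -> f72 from a selection model."""
    f0 = np.asarray(f0_list, dtype=float)
    if np.any((f0 <= 0.0) | (f0 >= 1.0)):
        raise ValueError("all initial frequencies must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    f72 = f0 + model.delta_f(f0)
    if model.noise_sd > 0:
        f72 = f72 + rng.normal(0.0, model.noise_sd, size=f0.shape)
    f72 = np.clip(f72, 0.0, 1.0)
    return [
        CompetitionRecord(condition=condition, f0=float(a), f72=float(b))
        for a, b in zip(f0, f72)
    ]


def sample_growth_curves(
    r: float,
    K: float,
    od0: float,
    dt_min: float = 30.0,
    t_end_h: float = 48.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Logistic OD600 time series sampled every ``dt_min`` minutes.

    OD(t) = K od0 e^{rt} / (K + od0 (e^{rt} - 1)) with ``r`` per hour, plus
    i.i.d. Gaussian measurement noise.  Returns columns ``t_min, od600``.
    """
    if r <= 0 or K <= 0 or od0 <= 0:
        raise ValueError("r, K and od0 must be positive")
    if dt_min <= 0:
        raise ValueError("sampling interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t_h = np.arange(0.0, t_end_h + 1e-9, dt_min / 60.0)
    e = np.exp(r * t_h)
    od = K * od0 * e / (K + od0 * (e - 1.0))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return pd.DataFrame({"t_min": t_h * 60.0, "od600": od})
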