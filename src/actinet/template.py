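"""Conductive templates for excitable-wave simulation.

An actin-bundle network image is reduced to a binary *conductive mask*: a
lattice whose nodes are either conductive (part of a bundle) or void.
Masks come from two sources:

* thresholding an RGB micrograph of a bundle network, channel by channel;
* the synthetic generator, which emulates regularly spaced aster-based
  bundle networks and provides engineered fixtures (straight channels and
  multi-arm junctions) with labelled input/output arm endpoints.

Coordinates are 0-based ``(row, col)``, row-major, origin at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import draw as skdraw
from skimage import measure, morphology

__all__ = [
    "ConductiveMask",
    "MaskStats",
    "NetworkRecipe",
    "NETWORK_KINDS",
    "threshold_rgb",
    "generate_network",
    "select_x_fixture",
    "mask_stats",
    "render_mask",
    "load_image",
    "save_mask",
    "load_mask",
    "save_mask_npz",
    "load_mask_npz",
]

#: default per-channel thresholds (strict ``>``) for bundle pixels
DEFAULT_R_MIN = 40
DEFAULT_G_MIN = 19
DEFAULT_B_MIN = 19

NETWORK_KINDS = (
    "aster_lattice",
    "straight_channel",
    "y_junction",
    "seven_channel_junction",
    "cross_junction",
)


@dataclass
class ConductiveMask:
    """Binary lattice of conductive nodes.

    Parameters
    ----------
    grid
        Boolean array, shape ``(n_rows, n_cols)``; True marks a conductive
        node.
    landmarks
        Optional named lattice coordinates, e.g. labelled arm endpoints of
        an engineered junction fixture (``{"x": (row, col), ...}``).
    """

    grid: np.ndarray
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("mask grid must be a non-empty 2-D array")
        if grid.dtype != bool:
            if not np.isin(grid, (0, 1)).all():
                raise ValueError("mask grid entries must be 0 or 1")
            grid = grid.astype(bool)
        self.grid = grid
        for name, (r, c) in self.landmarks.items():
            if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
                raise ValueError(f"landmark {name!r} at {(r, c)} is off-grid")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def conductive_count(self) -> int:
        return int(self.grid.sum())

    def __eq__(self, other) -> bool:  # landmark-insensitive
        return isinstance(other, ConductiveMask) and np.array_equal(
            self.grid, other.grid
        )


@dataclass(frozen=True)
class MaskStats:
    conductive_count: int
    fill_fraction: float
    n_components: int


@dataclass(frozen=True)
class NetworkRecipe:
    """Geometry recipe for :func:`generate_network`.

    ``spacing`` is the aster-lattice pitch in nodes, ``bundle_width`` the
    drawn bundle thickness in nodes (effective width is the odd number
    ``2*(bundle_width//2) + 1``), ``jitter`` the fractional displacement of
    aster centres, ``channel_length`` the fixture channel length in nodes.
    A single integer ``seed`` drives every stochastic element (centre
    jitter and presence/absence of individual connecting bundles).
    """

    kind: str
    shape: tuple[int, int] = (256, 256)
    spacing: int = 40
    bundle_width: int = 5
    jitter: float = 0.15
    channel_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(
                f"unknown network kind {self.kind!r}; expected one of {NETWORK_KINDS}"
            )
        if self.bundle_width < 3:
            raise ValueError(
                "bundle_width must be >= 3 nodes: narrower bundles quench "
                "excitation waves"
            )
        if self.spacing <= 2 * self.bundle_width:
            raise ValueError("spacing must exceed twice the bundle width")
        if not 0.0 <= self.jitter < 0.5:
            raise ValueError("jitter fraction must lie in [0, 0.5)")
        if min(self.shape) < 4 * self.bundle_width:
            raise ValueError("grid too small for the requested bundle width")


def threshold_rgb(
    img: np.ndarray,
    r_min: int = DEFAULT_R_MIN,
    g_min: int = DEFAULT_G_MIN,
    b_min: int = DEFAULT_B_MIN,
) -> ConductiveMask:
    """Convert an 8-bit image to a conductive mask.

    A pixel becomes conductive iff *all three* channel intensities strictly
    exceed their thresholds (``r > r_min and g > g_min and b > b_min``).
    Grayscale input is treated as ``r = g = b``. Non-8-bit input is
    rejected rather than silently rescaled.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit (uint8) image data, got dtype {img.dtype}; "
            "convert explicitly before thresholding"
        )
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("expected an RGB (H, W, 3) or grayscale (H, W) image")
    if img.size == 0:
        raise ValueError("empty image")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    grid = (r > r_min) & (g > g_min) & (b > b_min)
    return ConductiveMask(grid)


def mask_stats(mask: ConductiveMask, connectivity: int = 2) -> MaskStats:
    """Conductive count, fill fraction and 8-connected component count.

    8-connectivity (``connectivity=2``) is the default because thin
    diagonal bundles would fragment under 4-connectivity.
    """
    count = mask.conductive_count
    _, n_comp = measure.label(
        mask.grid, connectivity=connectivity, return_num=True
    )
    return MaskStats(
        conductive_count=count,
        fill_fraction=count / mask.grid.size,
        n_components=n_comp,
    )


# ---------------------------------------------------------------------------
# synthetic generation


def _thick_lines(shape, segments, width) -> np.ndarray:
    """Rasterise line segments and dilate them to the requested width."""
    canvas = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        rr, cc = skdraw.line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    radius = width // 2
    if radius > 0:
        canvas = morphology.dilation(canvas, morphology.disk(radius))
    return canvas


def _arm_endpoint(centre, angle, radius):
    r = int(round(centre[0] - radius * np.sin(angle)))
    c = int(round(centre[1] + radius * np.cos(angle)))
    return r, c


def _check_arm_separation(grid, hub, hub_radius, n_arms):
    """Degenerate-geometry guard: deleting the hub must leave one
    component per arm, otherwise the channels have merged into a blob."""
    pruned = grid.copy()
    rr, cc = skdraw.disk(hub, hub_radius, shape=grid.shape)
    pruned[rr, cc] = False
    _, n_comp = measure.label(pruned, connectivity=2, return_num=True)
    if n_comp != n_arms:
        raise ValueError(
            f"degenerate junction geometry: expected {n_arms} separable arms, "
            f"found {n_comp} components after hub removal"
        )


def _junction(shape, width, labels, angles, hub_extra=0):
    h, w = shape
    centre = (h // 2, w // 2)
    margin = 2 * width
    radius = min(h, w) // 2 - margin
    ends = [_arm_endpoint(centre, ang, radius) for ang in angles]
    grid = _thick_lines(shape, [(centre, e) for e in ends], width)
    if hub_extra > 0:
        rr, cc = skdraw.disk(centre, hub_extra, shape=shape)
        grid[rr, cc] = True
    _check_arm_separation(grid, centre, 3 * width, len(angles))
    landmarks = dict(zip(labels, ends))
    landmarks["hub"] = centre
    return ConductiveMask(grid, landmarks)


def _gen_straight_channel(recipe: NetworkRecipe) -> ConductiveMask:
    h, w = recipe.shape
    length = min(recipe.channel_length, w)
    width = 2 * (recipe.bundle_width // 2) + 1
    r0 = h // 2 - width // 2
    c0 = (w - length) // 2
    grid = np.zeros((h, w), dtype=bool)
    grid[r0 : r0 + width, c0 : c0 + length] = True
    mid = h // 2
    return ConductiveMask(
        grid, {"x": (mid, c0), "y": (mid, c0 + length - 1), "z": (mid, c0 + length - 1)}
    )


def _gen_y_junction(recipe: NetworkRecipe) -> ConductiveMask:
    h, w = recipe.shape
    width = recipe.bundle_width
    centre = (h // 2, w // 2)
    margin = 2 * width
    x_end = (margin, margin)
    y_end = (h - 1 - margin, margin)
    z_end = (h // 2, w - 1 - margin)
    grid = _thick_lines(
        (h, w), [(centre, x_end), (centre, y_end), (centre, z_end)], width
    )
    _check_arm_separation(grid, centre, 3 * width, 3)
    return ConductiveMask(
        grid, {"x": x_end, "y": y_end, "z": z_end, "hub": centre}
    )


def _gen_cross_junction(recipe: NetworkRecipe) -> ConductiveMask:
    angles = [np.pi, np.pi / 2, 0.0, -np.pi / 2]  # left, up, right, down
    return _junction(
        recipe.shape, recipe.bundle_width, ["x", "y", "z1", "z2"], angles
    )


def _gen_seven_channel_junction(recipe: NetworkRecipe) -> ConductiveMask:
    # seven bundles meeting at a central hub; arms x, y adjacent, z1..z5
    angles = [np.pi / 2 + k * 2 * np.pi / 7 for k in range(7)]
    labels = ["x", "y", "z1", "z2", "z3", "z4", "z5"]
    return _junction(
        recipe.shape,
        recipe.bundle_width,
        labels,
        angles,
        hub_extra=recipe.bundle_width,
    )


def _gen_aster_lattice(recipe: NetworkRecipe) -> ConductiveMask:
    """Jittered square lattice of aster centres joined by straight bundles.

    Orthogonally neighbouring centres are connected with high probability,
    diagonal neighbours with lower probability, giving each centre a
    star-like set of emanating bundles and the network a mixture of loops
    and dead ends, as in regularly spaced aster-based bundle networks.
    """
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.shape
    s = recipe.spacing
    n_r = max(2, h // s)
    n_c = max(2, w // s)
    off_r = (h - (n_r - 1) * s) // 2
    off_c = (w - (n_c - 1) * s) // 2
    jit = recipe.jitter * s
    centres = np.empty((n_r, n_c, 2))
    for i in range(n_r):
        for j in range(n_c):
            dr, dc = rng.uniform(-jit, jit, size=2)
            centres[i, j] = (
                np.clip(off_r + i * s + dr, 0, h - 1),
                np.clip(off_c + j * s + dc, 0, w - 1),
            )
    segments = []
    p_orth, p_diag = 0.9, 0.4
    for i in range(n_r):
        for j in range(n_c):
            here = centres[i, j]
            for di, dj, p in ((0, 1, p_orth), (1, 0, p_orth),
                              (1, 1, p_diag), (1, -1, p_diag)):
                i2, j2 = i + di, j + dj
                if 0 <= i2 < n_r and 0 <= j2 < n_c and rng.random() < p:
                    segments.append((here, centres[i2, j2]))
    grid = _thick_lines((h, w), segments, recipe.bundle_width)
    return ConductiveMask(grid)


_GENERATORS = {
    "aster_lattice": _gen_aster_lattice,
    "straight_channel": _gen_straight_channel,
    "y_junction": _gen_y_junction,
    "cross_junction": _gen_cross_junction,
    "seven_channel_junction": _gen_seven_channel_junction,
}


def generate_network(recipe: NetworkRecipe) -> ConductiveMask:
    """Generate a synthetic conductive mask; pure function of the recipe
    (including its seed)."""
    return _GENERATORS[recipe.kind](recipe)


def select_x_fixture(
    shape: tuple[int, int] = (64, 256), bundle_width: int = 5
) -> ConductiveMask:
    """Engineered fixture whose output arm is reachable from input ``x``
    only: a straight x->z channel plus a disconnected stub carrying the
    ``y`` input. Any downstream readout is then a function of x alone."""
    h, w = shape
    width = 2 * (bundle_width // 2) + 1
    grid = np.zeros(shape, dtype=bool)
    r_top = h // 4
    grid[r_top : r_top + width, 2 : w - 2] = True
    r_bot = 3 * h // 4
    stub_len = w // 3
    grid[r_bot : r_bot + width, 2 : 2 + stub_len] = True
    mid_top = r_top + width // 2
    mid_bot = r_bot + width // 2
    return ConductiveMask(
        grid,
        {"x": (mid_top, 4), "y": (mid_bot, 4), "z": (mid_top, w - 4)},
    )


# ---------------------------------------------------------------------------
# i/o


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF image; alpha channel, if any, is dropped."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] == 4:
        img = img[..., :3]
    return img


def render_mask(mask: ConductiveMask) -> np.ndarray:
    """Render a mask as an 8-bit grayscale image (0 = void, 255 = conductive)."""
    return np.where(mask.grid, 255, 0).astype(np.uint8)


def save_mask(mask: ConductiveMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG plus, if landmarks are present, a JSON
    sidecar ``<path>.landmarks.json``. Round-trips losslessly."""
    path = Path(path)
    iio.imwrite(path, render_mask(mask))
    if mask.landmarks:
        sidecar = path.with_suffix(path.suffix + ".landmarks.json")
        sidecar.write_text(
            json.dumps({k: list(v) for k, v in mask.landmarks.items()}, indent=1)
        )


def save_mask_npz(mask: ConductiveMask, path: str | Path) -> None:
    """Write a mask (and landmarks) as a compressed numeric container."""
    landmark_items = sorted(mask.landmarks.items())
    np.savez_compressed(
        path,
        grid=mask.grid,
        landmark_names=np.array([k for k, _ in landmark_items]),
        landmark_sites=np.array(
            [v for _, v in landmark_items], dtype=np.int64
        ).reshape(len(landmark_items), 2),
    )


def load_mask_npz(path: str | Path) -> ConductiveMask:
    with np.load(path) as data:
        landmarks = {
            str(name): (int(site[0]), int(site[1]))
            for name, site in zip(data["landmark_names"], data["landmark_sites"])
        }
        return ConductiveMask(data["grid"], landmarks)


def load_mask(path: str | Path) -> ConductiveMask:
    path = Path(path)
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    landmarks = {}
    sidecar = path.with_suffix(path.suffix + ".landmarks.json")
    if sidecar.exists():
        landmarks = {
            k: tuple(v) for k, v in json.loads(sidecar.read_text()).items()
        }
    return ConductiveMask(img > 127, landmarks)
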