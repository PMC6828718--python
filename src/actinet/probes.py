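"""Electrode recordings and per-step measurements.

Measurement conventions:

* An electrode at lattice site x records the potential
  ``p_x = sum_{y : |x - y| < 2} (u_y - v_y)`` over conductive nodes within
  Euclidean distance < 2 — the 3x3 neighbourhood (centre, four orthogonal
  neighbours at distance 1, four diagonal at sqrt(2)).
* A node counts as *excited* when ``u > 0.1`` (strict). The network
  activity A at a step is the excited-node count divided by the conductive
  node count.
* The frequency matrix of a run counts, per node, the steps on which the
  node was excited; it is then normalised by its global maximum, and
  *high-frequency domains* are the 8-connected components of nodes with
  normalised frequency strictly above 0.72.
* A spike in a potential trace is an upward crossing of a threshold
  followed by a local maximum; crossings within a refractory window of the
  previous spike are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure, morphology

from .fhn import EXCITED_THRESHOLD, FHNState
from .template import ConductiveMask

__all__ = [
    "ElectrodeArray",
    "FrequencyMatrix",
    "Domain",
    "SpikeTrain",
    "SpikeEvent",
    "record_potential",
    "update_activity",
    "update_frequency",
    "finalize_frequency",
    "extract_high_frequency_domains",
    "detect_spikes",
    "align_spike_events",
    "save_spike_trains",
    "load_spike_trains",
    "render_frequency_heatmap",
    "INPUT_PAIRS",
]

#: the three stimulated input pairs (x y); the quiescent pair 00 never
#: excites anything and is not simulated
INPUT_PAIRS = ("01", "10", "11")

#: default spike-detection threshold on the electrode potential p
SPIKE_THRESHOLD = 0.5
#: default refractory merge window, iterations
REFRACTORY_WINDOW = 300
#: spikes closer than this (iterations) across input pairs are simultaneous
SIMULTANEITY_WINDOW = 200
#: events further apart than this (iterations) are distinct
SEPARATION_WINDOW = 1000
#: normalised-frequency level (strict >) defining high-frequency domains
DOMAIN_THRESHOLD = 0.72
#: smallest domain reported, in nodes (suppresses single-pixel speckle)
MIN_DOMAIN_SIZE = 5


@dataclass(frozen=True)
class ElectrodeArray:
    """Labelled recording sites plus the two labelled input sites."""

    electrodes: tuple[tuple[str, tuple[int, int]], ...]
    input_sites: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")

    def validate_on_mask(self, mask: ConductiveMask) -> None:
        h, w = mask.shape
        for lab, (r, c) in list(self.electrodes) + list(self.input_sites.items()):
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"site {lab!r} at {(r, c)} is off-grid")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.electrodes]


def neighborhood_indices(
    mask: ConductiveMask, site: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Conductive (rows, cols) within Euclidean distance < 2 of ``site``."""
    r0, c0 = site
    h, w = mask.shape
    rr, cc = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= c < w and mask.grid[r, c]:
                rr.append(r)
                cc.append(c)
    return np.asarray(rr, dtype=int), np.asarray(cc, dtype=int)


def record_potential(state: FHNState, site: tuple[int, int]) -> float:
    """Potential p at an electrode: sum of (u - v) over the conductive 3x3
    neighbourhood of ``site``."""
    lat = state.lattice
    idx = lat.disc(site, 1.5)
    return float((state.u[idx] - state.v[idx]).sum())


def update_activity(state: FHNState) -> tuple[int, float]:
    """Excited-node count (u strictly > 0.1) and its fraction A of all
    conductive nodes (0 when the mask is empty)."""
    count = int(np.count_nonzero(state.u > EXCITED_THRESHOLD))
    n = state.lattice.n_nodes
    return count, (count / n if n else 0.0)


def update_frequency(counts: np.ndarray, state: FHNState) -> np.ndarray:
    """Increment each node's excitation count where u > 0.1 this step."""
    counts += state.u > EXCITED_THRESHOLD
    return counts


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-node excitation counts for one input pair, plus the
    max-normalised map (all-zero counts stay all-zero)."""

    input_pair: str
    counts: np.ndarray
    normalised: np.ndarray


def finalize_frequency(counts: np.ndarray, input_pair: str = "") -> FrequencyMatrix:
    counts = np.asarray(counts)
    peak = counts.max() if counts.size else 0
    norm = counts / peak if peak > 0 else np.zeros_like(counts, dtype=float)
    return FrequencyMatrix(input_pair, counts, norm)


@dataclass(frozen=True)
class Domain:
    """One high-frequency domain: its node set and centroid."""

    nodes: tuple[tuple[int, int], ...]
    size: int
    centroid: tuple[float, float]


def extract_high_frequency_domains(
    fm: FrequencyMatrix,
    threshold: float = DOMAIN_THRESHOLD,
    min_size: int = MIN_DOMAIN_SIZE,
) -> list[Domain]:
    """8-connected components of nodes with normalised frequency strictly
    above ``threshold``; components smaller than ``min_size`` are dropped."""
    hot = fm.normalised > threshold
    labels, n = measure.label(hot, connectivity=2, return_num=True)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_size:
            continue
        nodes = tuple((int(r), int(c)) for r, c in region.coords)
        out.append(
            Domain(nodes=nodes, size=int(region.area),
                   centroid=tuple(float(x) for x in region.centroid))
        )
    return out


@dataclass(frozen=True)
class SpikeTrain:
    electrode: str
    input_pair: str
    times: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("spike times must be strictly increasing")


def detect_spikes(
    steps: np.ndarray,
    p: np.ndarray,
    p_threshold: float = SPIKE_THRESHOLD,
    refractory_window: int = REFRACTORY_WINDOW,
    electrode: str = "",
    input_pair: str = "",
) -> SpikeTrain:
    """Threshold-crossing spike detector.

    Scans the trace for local maxima with ``p > p_threshold``; a maximum
    within ``refractory_window`` of the previously kept spike is merged
    into it (the earlier peak stands). Spike times are reported on the
    ``steps`` axis of the trace.
    """
    p = np.asarray(p, dtype=float)
    steps = np.asarray(steps)
    if p.size == 0:
        raise ValueError("empty trace")
    times: list[int] = []
    last = None
    for i in range(p.size):
        if p[i] <= p_threshold:
            continue
        left = p[i - 1] if i > 0 else -np.inf
        right = p[i + 1] if i + 1 < p.size else -np.inf
        if not (p[i] > left and p[i] >= right):
            continue
        t = int(steps[i])
        if last is not None and t - last <= refractory_window:
            continue
        times.append(t)
        last = t
    return SpikeTrain(electrode, input_pair, tuple(times))


@dataclass(frozen=True)
class SpikeEvent:
    """One aligned event across the three input-pair recordings: the event
    time and the 3-bit response vector (b01, b10, b11)."""

    time: int
    vector: tuple[int, int, int]


def align_spike_events(
    trains: Mapping[str, Iterable[int]] | Mapping[str, SpikeTrain],
    simultaneity_window: int = SIMULTANEITY_WINDOW,
    separation_window: int = SEPARATION_WINDOW,
) -> list[SpikeEvent]:
    """Merge spikes recorded under input pairs 01, 10 and 11 into events.

    Spikes whose times differ by less than ``simultaneity_window`` count as
    the same event; a spike within the window of two candidate events is
    assigned to the nearer anchor (earlier on a tie). Events closer than or
    equal to ``separation_window`` to the previously retained event are
    discarded as echoes of the same passage, so retained events are
    guaranteed to be more than ``separation_window`` apart.
    """
    spikes: list[tuple[int, str]] = []
    for h in INPUT_PAIRS:
        train = trains.get(h, ())
        times = train.times if isinstance(train, SpikeTrain) else train
        spikes.extend((int(t), h) for t in times)
    if not spikes:
        return []
    spikes.sort()
    # first pass: greedy anchors (first spike of each cluster)
    anchors: list[int] = []
    for t, _ in spikes:
        if not anchors or t - anchors[-1] >= simultaneity_window:
            anchors.append(t)
    anchors_arr = np.asarray(anchors)
    members: dict[int, set[str]] = {t: set() for t in anchors}
    for t, h in spikes:
        d = np.abs(anchors_arr - t)
        near = np.nonzero(d < simultaneity_window)[0]
        if near.size == 0:
            continue  # cannot happen: its own cluster anchor is within window
        best = near[np.argmin(d[near])]  # argmin takes the earlier on ties
        members[anchors[best]].add(h)
    events = []
    last_kept = None
    for t in anchors:
        if last_kept is not None and t - last_kept <= separation_window:
            continue
        vec = tuple(int(h in members[t]) for h in INPUT_PAIRS)
        events.append(SpikeEvent(time=t, vector=vec))
        last_kept = t
    return events


# ---------------------------------------------------------------------------
# i/o


def save_spike_trains(trains: Iterable[SpikeTrain], path) -> None:
    """Write spike trains as CSV (electrode, input_pair, step)."""
    rows = [
        {"electrode": tr.electrode, "input_pair": tr.input_pair, "step": t}
        for tr in trains
        for t in tr.times
    ]
    pd.DataFrame(rows, columns=["electrode", "input_pair", "step"]).to_csv(
        path, index=False
    )


def load_spike_trains(path) -> list[SpikeTrain]:
    df = pd.read_csv(path, dtype={"input_pair": str})
    out = []
    for (el, h), grp in df.groupby(["electrode", "input_pair"], sort=True):
        out.append(SpikeTrain(str(el), str(h), tuple(sorted(int(t) for t in grp["step"]))))
    return out


def render_frequency_heatmap(
    fm: FrequencyMatrix, path, threshold: float = DOMAIN_THRESHOLD
) -> None:
    """Render a normalised frequency matrix as a grayscale PNG with the
    high-frequency (> threshold) domains outlined in red."""
    img = np.repeat(
        (fm.normalised * 255).astype(np.uint8)[..., None], 3, axis=-1
    )
    hot = fm.normalised > threshold
    outline = hot & ~morphology.erosion(hot)
    img[outline] = (255, 0, 0)
    iio.imwrite(Path(path), img)
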