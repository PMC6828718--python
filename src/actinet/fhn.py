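"""Two-variable FitzHugh-Nagumo dynamics on a conductive mask.

The medium is the classic excitable two-variable reduction of
Hodgkin-Huxley membrane kinetics,

    du/dt = c1 * u * (u - a) * (1 - u) - c2 * u * v + I + D_u * lap(u)
    dv/dt = b * (u - v)

integrated with the explicit Euler method on the conductive nodes of a
:class:`~actinet.template.ConductiveMask`. ``u`` is the fast trans-membrane
potential (stable rest at 0, excited branch near 1, excitation threshold
``a``), ``v`` the slow recovery variable, ``I`` an external stimulation
current and ``D_u`` the conductance of the passive current spread.

The Laplacian is the five-node orthogonal stencil restricted to the mask:
flux to void or out-of-grid neighbours is dropped, which is the mirror
(no-flux, impermeable-boundary) condition. ``c2`` controls excitability:
raising it from 0.1 towards ~0.13 moves the medium from fully excitable to
sub-excitable and finally non-excitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from numba import njit

from .template import ConductiveMask

__all__ = [
    "SimulationParams",
    "StimulusEvent",
    "Lattice",
    "FHNState",
    "ProbeSpec",
    "RunRecord",
    "reaction",
    "masked_laplacian",
    "step",
    "run",
]

#: u level above which a node counts as excited (activity, frequency maps)
EXCITED_THRESHOLD = 0.1
#: u level rendered as wavefront in exported frames
FRAME_THRESHOLD = 0.04
#: frame export cadence in iterations
FRAME_EVERY = 150


@dataclass(frozen=True)
class SimulationParams:
    """Integration and kinetics parameters.

    Defaults are the reference parameterisation for actin-bundle network
    templates: Euler step ``dt = 0.015`` on a lattice with node spacing
    ``dx = 2``, conductance ``D_u = 1``, excitation threshold ``a = 0.13``,
    recovery rate ``b = 0.013``, activation coefficient ``c1 = 0.26`` and
    excitability control ``c2`` (0.1 fully excitable; 0.107 / 0.108
    sub-excitable; beyond ~0.13 non-excitable).
    """

    dt: float = 0.015
    dx: float = 2.0
    d_u: float = 1.0
    a: float = 0.13
    b: float = 0.013
    c1: float = 0.26
    c2: float = 0.1
    i_ext: float = 0.0
    n_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ValueError("dt and dx must be positive")
        if self.d_u < 0:
            raise ValueError("conductance D_u must be non-negative")
        if not 0 < self.a < 1:
            raise ValueError("excitation threshold a must lie in (0, 1)")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")


@dataclass(frozen=True)
class StimulusEvent:
    """Scheduled local stimulation.

    ``set_u`` overwrites ``u`` with ``amplitude`` on every conductive node
    within Euclidean distance ``radius`` of ``site`` (applied after the
    Euler update, for ``duration`` consecutive steps starting at
    ``at_step``). ``add_I`` instead injects ``amplitude`` into the external
    current at the same footprint while active. The default — a one-step
    supra-threshold kick of u = 1 in a radius-5 disc — encodes a logical
    True delivered at an input site.
    """

    site: tuple[int, int]
    radius: int = 5
    amplitude: float = 1.0
    at_step: int = 0
    duration: int = 1
    mode: str = "set_u"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("stimulus radius must be >= 1 node")
        if self.duration < 1:
            raise ValueError("stimulus duration must be >= 1 step")
        if self.mode not in ("set_u", "add_I"):
            raise ValueError("stimulus mode must be 'set_u' or 'add_I'")

    def active_at(self, t: int) -> bool:
        return self.at_step <= t < self.at_step + self.duration


class Lattice:
    """Flattened view of a mask's conductive nodes with neighbour tables.

    Node ``i`` lives at ``(rows[i], cols[i])``. ``nbr[i, k]`` is the index
    of the k-th orthogonal neighbour, or ``i`` itself when that neighbour
    is void or off-grid — so ``u[nbr].sum(1) - 4 u`` is automatically the
    no-flux masked Laplacian numerator.
    """

    def __init__(self, mask: ConductiveMask):
        grid = mask.grid
        self.mask = mask
        self.shape = grid.shape
        rows, cols = np.nonzero(grid)
        self.rows, self.cols = rows, cols
        self.n_nodes = rows.size
        index = np.full(grid.shape, -1, dtype=np.int64)
        index[rows, cols] = np.arange(self.n_nodes)
        self.index = index
        nbr = np.empty((self.n_nodes, 4), dtype=np.int64)
        h, w = grid.shape
        for k, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
            r2, c2 = rows + dr, cols + dc
            inside = (r2 >= 0) & (r2 < h) & (c2 >= 0) & (c2 < w)
            j = np.arange(self.n_nodes)  # default: reflect back to self
            cand = index[r2[inside], c2[inside]]
            tgt = j[inside]
            conductive = cand >= 0
            j[tgt[conductive]] = cand[conductive]
            nbr[:, k] = j
        self.nbr = nbr

    def node_at(self, site: tuple[int, int]) -> int:
        i = int(self.index[site])
        if i < 0:
            raise ValueError(f"site {site} is not conductive")
        return i

    def disc(self, site: tuple[int, int], radius: float) -> np.ndarray:
        """Flat indices of conductive nodes within Euclidean ``radius``."""
        d2 = (self.rows - site[0]) ** 2 + (self.cols - site[1]) ** 2
        return np.nonzero(d2 <= radius * radius)[0]

    def to_grid(self, values: np.ndarray, fill=0) -> np.ndarray:
        out = np.full(self.shape, fill, dtype=np.asarray(values).dtype)
        out[self.rows, self.cols] = values
        return out


@dataclass
class FHNState:
    """Fields ``u`` (potential) and ``v`` (recovery) over conductive nodes
    plus the iteration counter. Void nodes carry no state and read as 0."""

    u: np.ndarray
    v: np.ndarray
    t: int
    lattice: Lattice

    @classmethod
    def resting(cls, lattice: Lattice) -> "FHNState":
        n = lattice.n_nodes
        return cls(np.zeros(n), np.zeros(n), 0, lattice)

    def u_grid(self) -> np.ndarray:
        return self.lattice.to_grid(self.u, fill=0.0)

    def v_grid(self) -> np.ndarray:
        return self.lattice.to_grid(self.v, fill=0.0)

    def copy(self) -> "FHNState":
        return FHNState(self.u.copy(), self.v.copy(), self.t, self.lattice)


def reaction(u, v, i_ext, params: SimulationParams):
    """Pointwise kinetics: returns ``(du_dt, dv_dt)`` without diffusion.

    The cubic ``u (u - a) (1 - u)`` has stable fixed points at u = 0 and
    u = 1 and the unstable excitation threshold at u = a.
    """
    du = params.c1 * u * (u - params.a) * (1.0 - u) - params.c2 * u * v + i_ext
    dv = params.b * (u - v)
    return du, dv


def masked_laplacian(
    u: np.ndarray, mask: ConductiveMask, dx: float
) -> np.ndarray:
    """Five-node Laplacian on the mask with impermeable boundaries.

    Each conductive node sums ``u_neighbour - u_centre`` over its
    conductive orthogonal neighbours and divides by ``dx**2``; void or
    off-grid neighbours contribute zero flux (mirror condition)."""
    u = np.asarray(u, dtype=float)
    g = mask.grid
    acc = np.zeros_like(u)
    h, w = g.shape
    # per-direction masked differences, implemented with shifted slices
    pairs = (
        ((slice(1, h), slice(None)), (slice(0, h - 1), slice(None))),
        ((slice(0, h - 1), slice(None)), (slice(1, h), slice(None))),
        ((slice(None), slice(1, w)), (slice(None), slice(0, w - 1))),
        ((slice(None), slice(0, w - 1)), (slice(None), slice(1, w))),
    )
    for centre_sl, nb_sl in pairs:
        both = g[centre_sl] & g[nb_sl]
        diff = np.where(both, u[nb_sl] - u[centre_sl], 0.0)
        acc[centre_sl] += diff
    acc[~g] = 0.0
    return acc / (dx * dx)


def _apply_stimuli(state: FHNState, stimuli, i_field):
    """Returns (i_field possibly updated, list of active set_u stimuli)."""
    setters = []
    for s in stimuli:
        if not s.active_at(state.t):
            continue
        idx = state.lattice.disc(s.site, s.radius)
        if s.mode == "add_I":
            if np.isscalar(i_field):
                i_field = np.full(state.u.shape, float(i_field))
            i_field[idx] += s.amplitude
        else:
            setters.append((idx, s.amplitude))
    return i_field, setters


def step(
    state: FHNState,
    params: SimulationParams,
    stimuli: Sequence[StimulusEvent] = (),
) -> FHNState:
    """Advance one Euler step in place and return the state.

    Both derivatives are evaluated at the pre-step fields. Stimuli in
    ``set_u`` mode overwrite u at their footprint *after* the update.
    Raises ``FloatingPointError`` with the offending step and site if the
    fields leave the finite range.
    """
    lat, u, v = state.lattice, state.u, state.v
    i_field, setters = _apply_stimuli(state, stimuli, params.i_ext)
    lap = (u[lat.nbr].sum(axis=1) - 4.0 * u) / (params.dx * params.dx)
    du, dv = reaction(u, v, i_field, params)
    u += params.dt * (du + params.d_u * lap)
    v += params.dt * dv
    for idx, amplitude in setters:
        u[idx] = amplitude
    state.t += 1
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        bad = np.nonzero(~(np.isfinite(u) & np.isfinite(v)))[0][0]
        site = (int(lat.rows[bad]), int(lat.cols[bad]))
        raise FloatingPointError(
            f"non-finite field value at step {state.t}, site {site}"
        )
    return state


@dataclass(frozen=True)
class ProbeSpec:
    """What to measure during a run.

    ``electrodes`` is a list of ``(label, (row, col))`` recording sites;
    each records the potential p = sum of (u - v) over conductive nodes
    within Euclidean distance < 2 (the 3x3 neighbourhood) at every step.
    """

    electrodes: Sequence[tuple[str, tuple[int, int]]] = ()
    track_activity: bool = True
    track_frequency: bool = True
    frame_dir: str | Path | None = None
    frame_every: int = FRAME_EVERY


@dataclass
class RunRecord:
    """Everything a finished run produced."""

    params: SimulationParams
    traces: pd.DataFrame
    freq_counts: np.ndarray | None  # per-node excitation counts, grid shape
    excited_ever: np.ndarray  # grid bool: nodes with u > 0.1 at any step
    final_state: FHNState
    frames: list[tuple[int, Path]] = field(default_factory=list)
    n_conductive: int = 0


def _electrode_gather(lattice: Lattice, electrodes):
    """Concatenated 3x3-neighbourhood index table for fast reduceat sums."""
    idx_parts, offsets, labels = [], [0], []
    for label, (r, c) in electrodes:
        part = lattice.disc((r, c), 1.5)  # Euclidean < 2: the 3x3 block
        if part.size == 0:
            raise ValueError(f"electrode {label!r} at {(r, c)} touches no conductive node")
        idx_parts.append(part)
        offsets.append(offsets[-1] + part.size)
        labels.append(label)
    if not idx_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), []
    return np.concatenate(idx_parts), np.asarray(offsets[:-1]), labels


def _write_frame(path, lattice, u, threshold):
    """Wavefront (u > threshold) in red over conductive sites in black."""
    img = np.full(lattice.shape + (3,), 255, dtype=np.uint8)
    img[lattice.rows, lattice.cols] = 0
    hot = u > threshold
    img[lattice.rows[hot], lattice.cols[hot]] = (255, 0, 0)
    iio.imwrite(path, img)


@njit(cache=True)
def _integrate_chunk(
    u, v, nbr, i_field, dt, dx2, a, b, c1, c2, d_u,
    n_chunk, k0, set_idx, set_off, set_amp,
    e_idx, e_off, p_out, act_out, freq, excited_ever, thr,
):
    """Euler-integrate ``n_chunk`` steps in place, recording measurements
    into rows ``k0..`` of the output buffers. The active stimulus set is
    constant within a chunk. Returns the 1-based step at which a
    non-finite value was first seen, or -1 on success."""
    n = u.shape[0]
    lap = np.empty(n)
    n_set = set_off.shape[0] - 1
    n_el = e_off.shape[0] - 1
    rec_act = act_out.shape[0] > 0
    rec_freq = freq.shape[0] > 0
    rec_p = n_el > 0 and p_out.shape[0] > 0
    for k in range(n_chunk):
        for i in range(n):
            lap[i] = (
                u[nbr[i, 0]] + u[nbr[i, 1]] + u[nbr[i, 2]] + u[nbr[i, 3]]
                - 4.0 * u[i]
            ) / dx2
        for i in range(n):
            ui = u[i]
            vi = v[i]
            du = (
                c1 * ui * (ui - a) * (1.0 - ui)
                - c2 * ui * vi
                + i_field[i]
                + d_u * lap[i]
            )
            u[i] = ui + dt * du
            v[i] = vi + dt * (b * (ui - vi))
        for s in range(n_set):
            amp = set_amp[s]
            for m in range(set_off[s], set_off[s + 1]):
                u[set_idx[m]] = amp
        cnt = 0
        for i in range(n):
            if u[i] > thr:
                cnt += 1
                excited_ever[i] = True
                if rec_freq:
                    freq[i] += 1
        if rec_act:
            act_out[k0 + k] = cnt
        if rec_p:
            for j in range(n_el):
                ssum = 0.0
                for m in range(e_off[j], e_off[j + 1]):
                    ii = e_idx[m]
                    ssum += u[ii] - v[ii]
                p_out[k0 + k, j] = ssum
        if (k & 255) == 255:
            for i in range(n):
                if not np.isfinite(u[i]):
                    return k0 + k + 1
    for i in range(n):
        if not np.isfinite(u[i]):
            return k0 + n_chunk
    return -1


_MAX_CHUNK = 65_536


def run(
    mask: ConductiveMask,
    params: SimulationParams,
    stimuli: Sequence[StimulusEvent] = (),
    probes: ProbeSpec | None = None,
    initial_state: FHNState | None = None,
) -> RunRecord:
    """Integrate ``params.n_steps`` Euler steps on the mask.

    Fully deterministic given its inputs. Per-step measurements (electrode
    potentials, excited-node count, per-node excitation frequency, the
    cumulative excited set) are taken after each update; frames are
    exported every ``frame_every`` steps (sites with u > 0.04 rendered as
    wavefront) when a frame directory is given. The inner loop is a
    compiled kernel; a single :func:`step` applies the identical update
    rule and is the plain-numpy reference path.
    """
    probes = probes or ProbeSpec()
    lattice = (
        initial_state.lattice if initial_state is not None else Lattice(mask)
    )
    state = initial_state if initial_state is not None else FHNState.resting(lattice)
    for s in stimuli:
        lattice.node_at(s.site)  # all stimulus sites must be conductive

    n_steps = params.n_steps
    n = lattice.n_nodes
    e_idx, e_off_list, e_labels = _electrode_gather(lattice, probes.electrodes)
    n_el = len(e_labels)
    e_off = np.concatenate([e_off_list, [e_idx.size]]).astype(np.int64)
    p_out = np.empty((n_steps, n_el)) if n_el else np.empty((0, 0))
    act_out = (
        np.empty(n_steps, dtype=np.int64)
        if probes.track_activity
        else np.empty(0, dtype=np.int64)
    )
    freq = (
        np.zeros(n, dtype=np.int64)
        if probes.track_frequency
        else np.empty(0, dtype=np.int64)
    )
    excited_ever = np.zeros(n, dtype=np.bool_)
    frames: list[tuple[int, Path]] = []
    frame_dir = probes.frame_dir
    if frame_dir is not None:
        frame_dir = Path(frame_dir)
        frame_dir.mkdir(parents=True, exist_ok=True)

    u, v = state.u, state.v
    t0 = state.t
    dx2 = params.dx * params.dx

    # chunk boundaries: stimulus on/off switches, frame steps, chunk cap
    boundaries = {n_steps}
    for s in stimuli:
        for edge in (s.at_step - t0, s.at_step + s.duration - t0):
            if 0 < edge < n_steps:
                boundaries.add(edge)
    if frame_dir is not None:
        fe = probes.frame_every
        t_frame = ((t0 // fe) + 1) * fe
        while t_frame - t0 <= n_steps:
            boundaries.add(t_frame - t0)
            t_frame += fe
    boundaries = sorted(boundaries)

    k = 0
    bi = 0
    while k < n_steps:
        k_end = min(boundaries[bi], k + _MAX_CHUNK)
        if k_end <= k:
            bi += 1
            continue
        active = [s for s in stimuli if s.active_at(t0 + k)]
        i_field = np.full(n, float(params.i_ext))
        set_idx_parts, set_amp = [], []
        for s in active:
            idx = lattice.disc(s.site, s.radius)
            if s.mode == "add_I":
                i_field[idx] += s.amplitude
            else:
                set_idx_parts.append(idx)
                set_amp.append(s.amplitude)
        set_idx = (
            np.concatenate(set_idx_parts).astype(np.int64)
            if set_idx_parts
            else np.empty(0, dtype=np.int64)
        )
        set_off = np.concatenate(
            [[0], np.cumsum([p.size for p in set_idx_parts])]
        ).astype(np.int64)
        bad_step = _integrate_chunk(
            u, v, lattice.nbr, i_field,
            params.dt, dx2, params.a, params.b, params.c1, params.c2,
            params.d_u, k_end - k, k,
            set_idx, set_off, np.asarray(set_amp, dtype=float),
            e_idx.astype(np.int64), e_off, p_out, act_out, freq,
            excited_ever, EXCITED_THRESHOLD,
        )
        state.t = t0 + k_end
        if bad_step >= 0:
            bad = np.nonzero(~np.isfinite(u))[0]
            site = (
                (int(lattice.rows[bad[0]]), int(lattice.cols[bad[0]]))
                if bad.size
                else None
            )
            raise FloatingPointError(
                f"non-finite field value near step {t0 + bad_step}, site {site}"
            )
        if frame_dir is not None and state.t % probes.frame_every == 0:
            path = frame_dir / f"frame_{state.t:07d}.png"
            _write_frame(path, lattice, u, FRAME_THRESHOLD)
            frames.append((state.t, path))
        k = k_end
        while bi < len(boundaries) and boundaries[bi] <= k:
            bi += 1

    n_cond = lattice.n_nodes
    act_out = act_out if probes.track_activity else None
    freq = freq if probes.track_frequency else None
    p_out = p_out if n_el else None
    cols: dict[str, np.ndarray] = {"step": np.arange(t0 + 1, t0 + n_steps + 1)}
    for j, label in enumerate(e_labels):
        cols[label] = p_out[:, j]
    if act_out is not None:
        cols["active_count"] = act_out
        cols["activity"] = act_out / n_cond if n_cond else act_out * 0.0
    traces = pd.DataFrame(cols)
    return RunRecord(
        params=params,
        traces=traces,
        freq_counts=lattice.to_grid(freq) if freq is not None else None,
        excited_ever=lattice.to_grid(excited_ever, fill=False),
        final_state=state,
        frames=frames,
        n_conductive=n_cond,
    )
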