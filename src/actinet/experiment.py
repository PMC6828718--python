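"""End-to-end gate-discovery experiments.

An experiment takes one conductive mask, an electrode array and a
parameter set, simulates the three stimulated input pairs (01, 10, 11)
with identical parameters, and applies the requested readout analyses:

* ``structural`` — which labelled output arms the wavefronts reach;
* ``frequency`` — high-frequency domain maps and gate placements;
* ``activity``  — interval rules on the mean network activity;
* ``spiking``   — per-electrode spike alignment, gate census, hierarchy
  and two-output (half-adder / Toffoli-style) pairs.

The ``demo`` pipeline mirrors the reference workflow at reduced scale:
a seeded aster network, 30 auto-placed electrodes on conductive nodes
(electrodes 7 and 17 double as the stimulation inputs x and y), and the
full analysis suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fhn, gates, probes, template
from .fhn import ProbeSpec, RunRecord, SimulationParams, StimulusEvent
from .gates import ActivityGateRule, GateCensus
from .probes import INPUT_PAIRS, ElectrodeArray
from .template import ConductiveMask, NetworkRecipe

__all__ = [
    "ExperimentConfig",
    "ValidationFinding",
    "validate_config",
    "run_experiment",
    "run_input_pairs",
    "spiking_analysis",
    "frequency_analysis",
    "activity_analysis",
    "farthest_point_electrodes",
    "demo",
    "DEMO_N_STEPS",
]

EXPERIMENT_KINDS = ("structural", "frequency", "activity", "spiking", "all")

#: demo run length, iterations (long enough for the network to settle on
#: its activity limit cycle and emit many spike events)
DEMO_N_STEPS = 142_000


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    params: SimulationParams
    electrodes: ElectrodeArray
    experiment: str = "all"
    mask_path: str | None = None
    recipe: NetworkRecipe | None = None
    out_dir: str | Path | None = None
    seed: int = 0
    stimulus: dict = field(default_factory=dict)  # StimulusEvent overrides
    spike_threshold: float = probes.SPIKE_THRESHOLD
    refractory_window: int = probes.REFRACTORY_WINDOW
    simultaneity_window: int = probes.SIMULTANEITY_WINDOW
    separation_window: int = probes.SEPARATION_WINDOW
    settle_step: int | None = None
    activity_rules: Sequence[ActivityGateRule] | None = None
    export_frames: bool = False

    def load_mask(self) -> ConductiveMask:
        if self.mask_path is not None:
            return template.load_mask(self.mask_path)
        if self.recipe is not None:
            return template.generate_network(self.recipe)
        raise ValueError("config needs either a mask path or a network recipe")


@dataclass(frozen=True)
class ValidationFinding:
    level: str  # 'error' | 'warning'
    message: str


def validate_config(
    cfg: ExperimentConfig, mask: ConductiveMask | None = None
) -> list[ValidationFinding]:
    """Check config invariants; returns findings instead of raising."""
    findings: list[ValidationFinding] = []
    err = lambda m: findings.append(ValidationFinding("error", m))
    warn = lambda m: findings.append(ValidationFinding("warning", m))
    if cfg.experiment not in EXPERIMENT_KINDS:
        err(f"unknown experiment kind {cfg.experiment!r}")
    if cfg.mask_path is None and cfg.recipe is None:
        err("neither mask path nor network recipe given")
    if cfg.mask_path is not None and not Path(cfg.mask_path).exists():
        err(f"mask path {cfg.mask_path} does not exist")
    if not 0.09 <= cfg.params.c2 <= 0.13:
        warn(
            f"c2={cfg.params.c2} outside the usable excitability range "
            "0.09 (fully excitable) .. 0.13 (non-excitable)"
        )
    if cfg.recipe is not None and cfg.recipe.bundle_width < 3:
        warn("bundle width < 3 nodes quenches excitation waves")
    if mask is None and cfg.mask_path is None and cfg.recipe is not None:
        mask = template.generate_network(cfg.recipe)
    if mask is not None:
        h, w = mask.shape
        sites = list(cfg.electrodes.electrodes) + list(
            cfg.electrodes.input_sites.items()
        )
        for lab, (r, c) in sites:
            if not (0 <= r < h and 0 <= c < w):
                err(f"site {lab!r} at {(r, c)} is off-grid")
            elif not mask.grid[r, c]:
                err(f"site {lab!r} at {(r, c)} is on a void (non-conductive) node")
        if not {"x", "y"} <= set(cfg.electrodes.input_sites):
            err("input sites must include 'x' and 'y'")
    return findings


def farthest_point_electrodes(
    mask: ConductiveMask, n: int = 30, seed: int = 0
) -> ElectrodeArray:
    """Place ``n`` electrodes on conductive nodes by farthest-point
    sampling (seeded start), labelled E_1..E_n; electrodes 7 and 17 are
    also declared as the input sites x and y."""
    rr, cc = np.nonzero(mask.grid)
    if rr.size == 0:
        raise ValueError("empty mask")
    rng = np.random.default_rng(seed)
    pts = np.stack([rr, cc], axis=1).astype(float)
    chosen = [int(rng.integers(rr.size))]
    dmin = None
    for _ in range(1, n):
        d = np.hypot(pts[:, 0] - pts[chosen[-1], 0], pts[:, 1] - pts[chosen[-1], 1])
        dmin = d if dmin is None else np.minimum(dmin, d)
        chosen.append(int(np.argmax(dmin)))
    electrodes = tuple(
        (f"E{i + 1}", (int(rr[j]), int(cc[j]))) for i, j in enumerate(chosen)
    )
    sites = dict(electrodes)
    inputs = {
        "x": sites.get("E7", electrodes[0][1]),
        "y": sites.get("E17", electrodes[-1][1]),
    }
    return ElectrodeArray(electrodes=electrodes, input_sites=inputs)


def _pair_stimuli(h: str, inputs: Mapping, stim_kwargs: Mapping) -> list[StimulusEvent]:
    events = []
    if h[0] == "1":
        events.append(StimulusEvent(site=tuple(inputs["x"]), **stim_kwargs))
    if h[1] == "1":
        events.append(StimulusEvent(site=tuple(inputs["y"]), **stim_kwargs))
    return events


def run_input_pairs(
    mask: ConductiveMask,
    params: SimulationParams,
    electrodes: ElectrodeArray,
    stim_kwargs: Mapping | None = None,
    frame_dir: str | Path | None = None,
) -> dict[str, RunRecord]:
    """One simulation per input pair, identical parameters throughout."""
    stim_kwargs = dict(stim_kwargs or {})
    records = {}
    for h in INPUT_PAIRS:
        spec = ProbeSpec(
            electrodes=tuple(electrodes.electrodes),
            frame_dir=None if frame_dir is None else Path(frame_dir) / h,
        )
        records[h] = fhn.run(
            mask,
            params,
            stimuli=_pair_stimuli(h, electrodes.input_sites, stim_kwargs),
            probes=spec,
        )
    return records


def spiking_analysis(
    records: Mapping[str, RunRecord],
    electrode_labels: Sequence[str],
    spike_threshold: float = probes.SPIKE_THRESHOLD,
    refractory_window: int = probes.REFRACTORY_WINDOW,
    simultaneity_window: int = probes.SIMULTANEITY_WINDOW,
    separation_window: int = probes.SEPARATION_WINDOW,
) -> GateCensus:
    """Spike detection, cross-pair alignment and gate census for every
    electrode."""
    events_by_electrode = {}
    for el in electrode_labels:
        trains = {}
        for h in INPUT_PAIRS:
            tr = records[h].traces
            trains[h] = probes.detect_spikes(
                tr["step"].to_numpy(),
                tr[el].to_numpy(),
                p_threshold=spike_threshold,
                refractory_window=refractory_window,
                electrode=el,
                input_pair=h,
            )
        events_by_electrode[el] = probes.align_spike_events(
            trains,
            simultaneity_window=simultaneity_window,
            separation_window=separation_window,
        )
    return gates.spiking_gate_census(events_by_electrode)


def frequency_analysis(
    records: Mapping[str, RunRecord],
    domain_threshold: float = probes.DOMAIN_THRESHOLD,
    min_domain_size: int = probes.MIN_DOMAIN_SIZE,
    colocate_radius: int = 10,
):
    """Frequency matrices, high-frequency domains per pair, and gate
    placements."""
    shape = next(iter(records.values())).excited_ever.shape
    domains_by_pair = {}
    matrices = {}
    for h in INPUT_PAIRS:
        fm = probes.finalize_frequency(records[h].freq_counts, input_pair=h)
        matrices[h] = fm
        domains_by_pair[h] = probes.extract_high_frequency_domains(
            fm, threshold=domain_threshold, min_size=min_domain_size
        )
    placements = gates.frequency_gate_placement(
        domains_by_pair, shape, colocate_radius=colocate_radius
    )
    return matrices, domains_by_pair, placements


def activity_analysis(
    records: Mapping[str, RunRecord],
    rules: Sequence[ActivityGateRule] | None = None,
    settle_step: int | None = None,
    c2: float = 0.1,
):
    if rules is None:
        rules = gates.DEFAULT_ACTIVITY_RULES.get(c2, ())
    if settle_step is None:
        settle_step = gates.DEFAULT_SETTLE_STEPS.get(c2, 80_000)
    traces = {h: records[h].traces for h in INPUT_PAIRS}
    return gates.activity_gates(traces, rules, settle_step)


def _census_json(census: GateCensus) -> dict:
    return {
        "table": census.table.reset_index().to_dict(orient="records"),
        "summary": {
            col: {k: float(v) for k, v in census.summary[col].items()}
            for col in census.summary.columns
        },
        "hierarchy": [list(g) for g in census.hierarchy],
        "hierarchy_string": census.hierarchy_string(),
        "select_total": census.select_total,
        "xor_total": census.xor_total,
        "events": {
            el: [{"time": ev.time, "vector": list(ev.vector)} for ev in evs]
            for el, evs in census.events_by_electrode.items()
        },
    }


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured experiment end to end; returns the report bundle
    (and writes it to ``cfg.out_dir`` when given).

    The bundle always contains the manifest (every numerically relevant
    parameter); analyses are included according to the experiment kind.
    """
    mask = cfg.load_mask()
    findings = validate_config(cfg, mask)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError(
            "invalid experiment config: " + "; ".join(f.message for f in errors)
        )

    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    records = run_input_pairs(
        mask,
        cfg.params,
        cfg.electrodes,
        stim_kwargs=cfg.stimulus,
        frame_dir=(out_dir / "frames") if (out_dir and cfg.export_frames) else None,
    )

    bundle: dict = {
        "manifest": {
            "params": asdict(cfg.params),
            "experiment": cfg.experiment,
            "seed": cfg.seed,
            "recipe": asdict(cfg.recipe) if cfg.recipe else None,
            "mask_path": cfg.mask_path,
            "stimulus": dict(cfg.stimulus),
            "electrodes": [[lab, list(site)] for lab, site in cfg.electrodes.electrodes],
            "input_sites": {k: list(v) for k, v in cfg.electrodes.input_sites.items()},
            "spike_threshold": cfg.spike_threshold,
            "refractory_window": cfg.refractory_window,
            "simultaneity_window": cfg.simultaneity_window,
            "separation_window": cfg.separation_window,
            "settle_step": cfg.settle_step,
            "n_conductive": mask.conductive_count,
            "warnings": [f.message for f in findings if f.level == "warning"],
        }
    }

    want = lambda kind: cfg.experiment in (kind, "all")
    if want("structural") and {"x", "y"} <= set(mask.landmarks):
        res = gates.structural_truth_table(
            mask, cfg.params, stim_kwargs=cfg.stimulus
        )
        bundle["structural"] = {
            "excited": {h: list(v) for h, v in res.excited.items()},
            "functions": {k: v.value for k, v in res.functions.items()},
            "non_functional": res.non_functional,
        }
    if want("frequency"):
        _, domains, placements = frequency_analysis(records)
        bundle["frequency"] = {
            "domains": {
                h: [
                    {"size": d.size, "centroid": list(d.centroid)}
                    for d in domains[h]
                ]
                for h in INPUT_PAIRS
            },
            "placements": {
                g.value: [
                    {"size": len(p.nodes), "centroid": list(p.centroid)}
                    for p in ps
                ]
                for g, ps in placements.items()
            },
        }
    if want("activity"):
        settle = cfg.settle_step
        if settle is None:
            settle = min(
                gates.DEFAULT_SETTLE_STEPS.get(cfg.params.c2, 80_000),
                cfg.params.n_steps // 2,
            )
        report = activity_analysis(
            records, rules=cfg.activity_rules, settle_step=settle, c2=cfg.params.c2
        )
        bundle["activity"] = {
            "mean_activity": dict(report.mean_activity),
            "rules": [
                {
                    "interval": [r.rule.lo, r.rule.hi],
                    "gate": r.rule.gate.value,
                    "fired": list(r.fired),
                    "induced_gate": r.induced_gate.value,
                    "matches": r.matches,
                }
                for r in report.rules
            ],
        }
    if want("spiking"):
        census = spiking_analysis(
            records,
            cfg.electrodes.labels,
            spike_threshold=cfg.spike_threshold,
            refractory_window=cfg.refractory_window,
            simultaneity_window=cfg.simultaneity_window,
            separation_window=cfg.separation_window,
        )
        bundle["spiking"] = _census_json(census)
        bundle["compound"] = [
            {"kind": f.kind, "electrodes": list(f.electrodes), "times": list(f.times)}
            for f in gates.compound_gate_report(
                census.events_by_electrode, cfg.simultaneity_window
            )
        ]

    if out_dir is not None:
        (out_dir / "report.json").write_text(
            json.dumps(bundle, indent=1, sort_keys=True)
        )
        for h, rec in records.items():
            rec.traces.to_csv(out_dir / f"traces_{h}.csv", index=False)
        if "spiking" in bundle:
            census_df = pd.DataFrame(bundle["spiking"]["table"])
            census_df.to_csv(out_dir / "census.csv", index=False)
    return bundle


def demo(
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_electrodes: int = 30,
    n_steps: int = DEMO_N_STEPS,
    c2: float = 0.1,
    out_dir: str | Path | None = None,
    experiment: str = "all",
) -> dict:
    """Full synthetic pipeline: seeded aster network, auto-placed
    electrodes, all gate analyses."""
    recipe = NetworkRecipe(kind="aster_lattice", shape=shape, seed=seed)
    mask = template.generate_network(recipe)
    electrodes = farthest_point_electrodes(mask, n=n_electrodes, seed=seed)
    cfg = ExperimentConfig(
        params=SimulationParams(n_steps=n_steps, c2=c2),
        electrodes=electrodes,
        experiment=experiment,
        recipe=recipe,
        out_dir=out_dir,
        seed=seed,
    )
    return run_experiment(cfg)
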