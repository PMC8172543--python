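"""End-to-end per-variant analysis: network → transients → pathways → report.

One configuration drives the whole chain for every donor/sensor variant:
build the rate network from structure, integrate the classical master
equation, apply (or fit) the quantum correction, extract peak metrics, and
decompose the sensor-arriving energy into pathway classes. All randomness
fans out from one global seed through a deterministic splitter so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calibration import fit_quantum_correction
from .master_eq import default_grid, integrate_master_equation, peak_metrics
from .pathway_decomp import exact_pathway_fractions, mc_pathway_fractions, \
    sample_jump_chain
from .structure_net import HEATER_POOL, EnergyNetwork, TransportParams, \
    apply_quantum_correction, assemble_network, detect_heater_contacts, \
    detect_hydrogen_bonds, parse_pdb, prune_contacts
from .synthetic_data import EnsembleSpec, VariantSpec, make_idealized_hairpin, \
    make_variants


@dataclass
class AnalysisConfig:
    structure_source: str = "idealized"   # "idealized" or a PDB file path
    n_res: int = 12
    variants: list[VariantSpec] = field(default_factory=make_variants)
    params: TransportParams = field(default_factory=TransportParams)
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    experimental_peak_times: dict[str, float] | None = None
    prune_fraction: float = 0.0
    n_walkers: int = 200_000
    t_max: float = 50.0
    dt: float = 0.05
    out_dir: str = "vetflow_out"
    seed: int = 1

    def __post_init__(self):
        if self.structure_source != "idealized" and \
                not Path(self.structure_source).exists():
            raise FileNotFoundError(self.structure_source)
        if not 0 <= self.prune_fraction <= 1:
            raise ValueError("prune_fraction must be in [0, 1]")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML file (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "variants" in kwargs:
        kwargs["variants"] = [VariantSpec(**v) for v in kwargs["variants"]]
    if "params" in kwargs:
        kwargs["params"] = TransportParams(**kwargs["params"])
    if "ensemble" in kwargs:
        kwargs["ensemble"] = EnsembleSpec(**kwargs["ensemble"])
    return AnalysisConfig(**kwargs)


def stage_seeds(global_seed: int, stages: list[str]) -> dict[str, int]:
    """Deterministically split one global seed into independent stage seeds."""
    children = np.random.SeedSequence(global_seed).spawn(len(stages))
    return {s: int(c.generate_state(1)[0] % 2**31)
            for s, c in zip(stages, children)}


def build_variant_network(config: AnalysisConfig,
                          variant: VariantSpec) -> EnergyNetwork:
    """Structure → HB/HC detection → assembled classical rate network."""
    if config.structure_source == "idealized":
        structure = make_idealized_hairpin(config.n_res, variant=variant)
    else:
        structure = parse_pdb(Path(config.structure_source).read_text())
    p = config.params
    hb = detect_hydrogen_bonds(structure, p.hb_cutoff, p.hb_angle_min)
    hc = detect_heater_contacts(structure, variant.donor, p.hc_cutoff)
    net = assemble_network(structure, hb, hc, p, heater_index=variant.donor)
    return net


def run_variant_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis for every variant and write a report bundle.

    Per variant the bundle holds the network (JSON), classical and
    quantum-corrected trajectories (CSV), peak summaries (JSON), pathway
    fractions (CSV) with the 50 ps shares (JSON), and a run log echoing every
    parameter and derived seed. Re-running the same config reproduces the
    numeric outputs exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed,
                        ["prune", *(f"mc:{v.name}" for v in config.variants)])
    grid = default_grid(config.t_max, config.dt)

    networks: dict[str, EnergyNetwork] = {}
    sensors: dict[str, object] = {}
    for v in config.variants:
        try:
            net = build_variant_network(config, v)
            if config.prune_fraction > 0:
                net = prune_contacts(net, fraction=config.prune_fraction,
                                     seed=seeds["prune"])
            networks[v.name] = net
            sensors[v.name] = v.sensor
        except Exception as exc:
            raise RuntimeError(f"stage build-net failed for {v.name}") from exc

    # quantum correction: fit globally if experimental peaks given, else use Q
    if config.experimental_peak_times:
        try:
            qfit = fit_quantum_correction(networks,
                                          config.experimental_peak_times,
                                          sensors, grid=grid)
        except Exception as exc:
            raise RuntimeError("stage fit-q failed") from exc
        q = qfit.params["Q"]
        qfit_dict = qfit.to_dict()
    else:
        q = config.params.Q
        qfit_dict = None

    report: dict = {"variants": {}, "Q": q, "q_fit": qfit_dict,
                    "seeds": seeds, "version": __version__}
    for v in config.variants:
        vdir = out / v.name
        vdir.mkdir(exist_ok=True)
        net = networks[v.name]
        try:
            classical = integrate_master_equation(net, grid=grid)
            quantum = integrate_master_equation(
                apply_quantum_correction(net, q), grid=grid)
            ens = sample_jump_chain(net, HEATER_POOL, v.sensor,
                                    config.n_walkers, config.t_max,
                                    seed=seeds[f"mc:{v.name}"])
            mc = mc_pathway_fractions(ens, grid)
            exact = exact_pathway_fractions(net, HEATER_POOL, v.sensor, grid)
        except Exception as exc:
            raise RuntimeError(f"stage analysis failed for {v.name}") from exc

        (vdir / "network.json").write_text(net.to_json())
        classical.to_frame().to_csv(vdir / "traj_classical.csv", index=False)
        quantum.to_frame().to_csv(vdir / "traj_quantum.csv", index=False)
        peaks = {"classical": peak_metrics(classical).to_dict(),
                 "quantum": peak_metrics(quantum).to_dict()}
        (vdir / "peaks.json").write_text(json.dumps(peaks, indent=1))
        exact.to_frame().to_csv(vdir / "pathways_exact.csv", index=False)
        mc.to_frame().to_csv(vdir / "pathways_mc.csv", index=False)
        summary = {
            "exact_at_50ps": exact.at(config.t_max),
            "mc_at_50ps": mc.at(config.t_max),
            "sensor_peak_classical_ps":
                peaks["classical"][str(v.sensor)]["peak_time_ps"],
            "sensor_peak_quantum_ps":
                peaks["quantum"][str(v.sensor)]["peak_time_ps"],
        }
        (vdir / "pathway_summary.json").write_text(json.dumps(summary, indent=1))
        report["variants"][v.name] = summary

    log = {"config": _config_to_jsonable(config), "Q": q,
           "seeds": seeds, "version": __version__}
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _config_to_jsonable(config: AnalysisConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj
    return enc(config)
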