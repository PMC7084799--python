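"""End-to-end analysis pipeline: I/O → frames → geometry → RIN → energetics.

One YAML config drives a batch run over named variant ensembles (e.g.
wild-type plus point mutants).  Per variant the pipeline writes the RMSD
series, per-residue RMSF, the residue interaction network (GraphML + CSV),
per-frame and summary binding-energy tables and per-residue/per-domain
decompositions; across variants it writes the interaction-type comparison
table and RIN difference reports against the first (reference) variant,
plus a manifest with the config hash and seed for provenance.

Config layout::

    parameters: params.tsv        # optional if ensembles are PQR-parameterized
    domains: domains.yaml         # optional
    ensembles:
      wild_type: wt.pdb
      mutant: mut.pdb
    dt: 200.0                     # ps between stored frames
    window: {start: 0.0, end: 7800.0, stride: 200.0}
    criterion: {overlap_threshold: -0.4, include_hydrogens: true}
    pb: {grid_spacing: 0.8, solute_dielectric: 2.0}
    solvation: true
    output: outdir
    seed: 1
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact_network import ContactCriterion, build_rin, compare_rins, export_rin
from .decomposition import (
    domain_aggregate,
    interaction_type_table,
    per_residue_decomposition,
)
from .energetics import PBSettings, ensemble_binding_energy
from .ensemble_io import (
    DomainMap,
    Ensemble,
    FrameWindow,
    assign_parameters,
    load_domain_map,
    read_ensemble,
    read_parameter_table,
)
from .superposition import rmsd_series, rmsf_per_residue

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("ppimutscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated inputs of one batch run."""

    ensembles: dict[str, Path]
    dt: float
    output: Path
    parameters: Path | None = None
    domains: Path | None = None
    window: FrameWindow | None = None
    criterion: ContactCriterion = field(default_factory=ContactCriterion)
    pb: PBSettings = field(default_factory=PBSettings)
    solvation: bool = True
    seed: int = 0
    domain_pairs: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.ensembles:
            raise PipelineError("config: no ensembles listed")
        for name, path in self.ensembles.items():
            if not Path(path).exists():
                raise PipelineError(f"config: ensemble {name!r} path {path} missing")
        for label, p in (("parameters", self.parameters), ("domains", self.domains)):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} path {p} missing")
        if self.dt <= 0:
            raise PipelineError("config: dt must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML pipeline config."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(key):
        return (base / raw[key]) if key in raw and raw[key] else None

    window = None
    if "window" in raw:
        w = raw["window"]
        window = FrameWindow(float(w["start"]), float(w["end"]), float(w["stride"]))
    crit = ContactCriterion(**raw.get("criterion", {}))
    pb = PBSettings(**raw.get("pb", {}))
    cfg = PipelineConfig(
        ensembles={k: base / v for k, v in raw["ensembles"].items()},
        dt=float(raw.get("dt", 1.0)),
        output=base / raw.get("output", "ppimutscan_out"),
        parameters=_p("parameters"),
        domains=_p("domains"),
        window=window,
        criterion=crit,
        pb=pb,
        solvation=bool(raw.get("solvation", True)),
        seed=int(raw.get("seed", 0)),
        domain_pairs=[tuple(p) for p in raw.get("domain_pairs", [])],
    )
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    def _default(o):
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), default=_default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out

        return wrapped

    return deco


@_stage("load")
def _load_variants(config: PipelineConfig) -> dict[str, Ensemble]:
    table = read_parameter_table(config.parameters) if config.parameters else None
    out = {}
    for name, path in config.ensembles.items():
        ens = read_ensemble(path, dt=config.dt)
        if table is not None:
            top = assign_parameters(ens.topology, table)
            ens = Ensemble(top, ens.coordinates, ens.times)
        out[name] = ens
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis batch; returns the output directory.

    Reruns with the same config and seed are content-identical.  Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    variants = _load_variants(config)
    domains: DomainMap | None = (
        load_domain_map(config.domains) if config.domains else None
    )

    rins = {}
    energies = {}
    for name, ens in variants.items():
        vdir = out / name
        vdir.mkdir(exist_ok=True)

        @_stage(f"geometry[{name}]")
        def _geometry(ens=ens, vdir=vdir):
            rmsd = rmsd_series(ens)
            pd.DataFrame(rmsd, columns=["time_ps", "rmsd_A"]).to_csv(
                vdir / "rmsd.csv", index=False
            )
            if ens.n_frames >= 2:
                rmsf = rmsf_per_residue(ens, group_by_chain=True, window=config.window)
                rows = [
                    {
                        "chain": c,
                        "residue_number": r,
                        "residue_name": ens.topology.residue_name_of(c, r),
                        "rmsf_A": v,
                    }
                    for (c, r), v in sorted(rmsf.items())
                ]
                pd.DataFrame(rows).to_csv(vdir / "rmsf.csv", index=False)

        @_stage(f"rin[{name}]")
        def _rin(ens=ens, vdir=vdir):
            rin = build_rin(ens, window=config.window, criterion=config.criterion)
            export_rin(rin, vdir / "rin.graphml")
            export_rin(rin, vdir / "rin.csv")
            return rin

        @_stage(f"energy[{name}]")
        def _energy(ens=ens, vdir=vdir):
            res = ensemble_binding_energy(
                ens,
                window=config.window,
                settings=config.pb,
                include_solvation=config.solvation,
                seed=config.seed,
            )
            rows = [
                {"frame": k, "time_ps": t, **terms.as_dict()}
                for k, (t, terms) in enumerate(zip(res.times, res.per_frame))
            ]
            pd.DataFrame(rows).to_csv(vdir / "energy_frames.csv", index=False)
            pd.DataFrame(
                {"mean": res.mean.as_dict(), "bootstrap_se": res.uncertainty.as_dict()}
            ).to_csv(vdir / "energy_summary.csv")
            return res

        @_stage(f"decomposition[{name}]")
        def _decomp(ens=ens, vdir=vdir):
            per_res = per_residue_decomposition(
                ens,
                window=config.window,
                settings=config.pb,
                include_solvation=config.solvation,
            )
            per_res.sorted_by_magnitude().to_csv(vdir / "per_residue.csv", index=False)
            if domains is not None:
                domain_aggregate(per_res, domains, pairs=config.domain_pairs or None).to_csv(
                    vdir / "per_domain.csv", index=False
                )

        _geometry()
        rins[name] = _rin()
        energies[name] = _energy()
        _decomp()

    @_stage("comparison")
    def _compare():
        interaction_type_table(energies, formatted=True).to_csv(out / "interaction_types.csv")
        names = list(variants)
        ref = names[0]
        for other in names[1:]:
            diff = compare_rins(rins[ref], rins[other], domains=domains)
            rows = [
                {"chain": n[0], "residue_number": n[1], "degree_delta": d}
                for n, d in diff.top_degree_gains()
            ]
            pd.DataFrame(rows).to_csv(out / f"rin_diff_{ref}_vs_{other}.csv", index=False)

    _compare()

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "variants": sorted(variants),
        "n_frames": {k: int(v.n_frames) for k, v in variants.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
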