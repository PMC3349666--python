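"""Stability rules, oligomer comparison, and the end-to-end pipeline.

An aggregate is called *unstable* when its CA RMSD exceeds 5 A (strictly)
over the equilibrated window — visibly disordered structures in the
underlying simulation work plateau near 20 A, stable zippers near 2.5 A.
The comparison across oligomer schemes ("m-n" organizations of the
hexamer's strands) orders the stable schemes by size, mirroring the logic
by which the single-sheet trimer (3-0) and the pentamer (3-2) emerge as
aggregation intermediates.  MM-PBSA free energies are consumed as printed
numbers only; the solver is out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as mx
from .pdbio import Trajectory, read_pdb, write_pdb
from .synthetic import FluctuationSpec, ZipperGeometry, build_ideal_zipper, generate_trajectory
from .topology import (
    SCHEME_LABELS,
    build_hexamer_topology,
    extract_oligomer,
)

__all__ = [
    "StabilityRule",
    "StabilityVerdict",
    "classify_stability",
    "relative_energy",
    "SimulationRecord",
    "VEALYL_SIMULATION_TABLE",
    "summarize_table1",
    "OligomerComparison",
    "compare_oligomers",
    "run_pipeline",
    "RMSD_INSTABILITY_THRESHOLD",
]

logger = logging.getLogger(__name__)

RMSD_INSTABILITY_THRESHOLD = 5.0  # A; structures beyond this are disordered


@dataclass(frozen=True)
class StabilityRule:
    """How an RMSD series is turned into a verdict.

    ``statistic`` is the summary applied to the post-burn-in window
    (``"mean"`` matches classifying whole runs by their plateau RMSD;
    ``"max"`` is stricter).  ``burn_in`` is the leading fraction of frames
    discarded as equilibration.
    """

    threshold: float = RMSD_INSTABILITY_THRESHOLD
    statistic: str = "mean"
    burn_in: float = 0.0


@dataclass(frozen=True)
class StabilityVerdict:
    mean_rmsd: float
    max_rmsd: float
    stable: bool
    basis: str


def classify_stability(
    rmsd_series: Sequence[float] | np.ndarray,
    rule: StabilityRule = StabilityRule(),
) -> StabilityVerdict:
    """Stable unless the windowed RMSD statistic strictly exceeds the threshold."""
    rmsd = np.asarray(rmsd_series, dtype=float)
    if rmsd.size == 0:
        raise ValueError("RMSD series is empty")
    start = int(np.floor(rule.burn_in * rmsd.size))
    window = rmsd[start:] if start < rmsd.size else rmsd[-1:]
    stat = float(window.mean() if rule.statistic == "mean" else window.max())
    return StabilityVerdict(
        mean_rmsd=float(window.mean()),
        max_rmsd=float(window.max()),
        stable=not stat > rule.threshold,
        basis=(
            f"unstable iff {rule.statistic} CA RMSD over the last "
            f"{100 * (1 - rule.burn_in):.0f}% of frames > {rule.threshold} A"
        ),
    )


def relative_energy(mean_a: float, mean_b: float) -> float:
    """Relative free energy A - B (kcal/mol); more negative = A more stable.

    E.g. the MM-PBSA means of the two trimer organizations,
    -677.70 (3-0) and -657.31 (2-1) kcal/mol, give -20.39 kcal/mol in
    favour of the single-sheet trimer.
    """
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ValueError("energies must be finite")
    return float(mean_a) - float(mean_b)


# ---------------------------------------------------------------------------
# Simulation-condition bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationRecord:
    """One simulated system: peptide sequence, organization, sampling."""

    sequence: str
    organization: str
    n_trajectories: int
    total_time_ns: float
    counter_ions: str = "/"
    n_waters: int = 0


#: Simulation conditions of the wild-type oligomer series and the glycine
#: mutants (trajectory counts and per-system total sampling).
VEALYL_SIMULATION_TABLE: tuple[SimulationRecord, ...] = (
    SimulationRecord("VEALYL", "1-1", 5, 100, "/", 1270),
    SimulationRecord("VEALYL", "2-0", 5, 100, "/", 1270),
    SimulationRecord("VEALYL", "2-1", 5, 100, "/", 1905),
    SimulationRecord("VEALYL", "3-0", 5, 100, "/", 1905),
    SimulationRecord("VEALYL", "2-2", 5, 100, "/", 2543),
    SimulationRecord("VEALYL", "3-1", 5, 100, "/", 2543),
    SimulationRecord("VEALYL", "3-2", 5, 100, "/", 3178),
    SimulationRecord("VEALYL", "3-3", 10, 200, "6 Na+", 3813),
    SimulationRecord("GEALYL", "3-3", 5, 100, "/", 3815),
    SimulationRecord("VGALYL", "3-3", 5, 100, "6 Na+", 3813),
    SimulationRecord("VEGLYL", "3-3", 5, 100, "6 Na+", 3811),
    SimulationRecord("VEAGYL", "3-3", 5, 100, "6 Na+", 3815),
    SimulationRecord("VEALGL", "3-3", 5, 100, "6 Na+", 3811),
    SimulationRecord("VEALYG", "3-3", 5, 100, "6 Na+", 3810),
    SimulationRecord("VEGGYL", "3-3", 5, 100, "6 Na+", 3811),
)


def summarize_table1(
    records: Iterable[SimulationRecord] = VEALYL_SIMULATION_TABLE,
) -> dict[str, float]:
    """Totals over the simulation-condition table: sampled time (us),
    trajectory count and system count."""
    records = list(records)
    return {
        "total_time_us": sum(r.total_time_ns for r in records) / 1000.0,
        "total_trajectories": sum(r.n_trajectories for r in records),
        "n_systems": len(records),
    }


# ---------------------------------------------------------------------------
# Oligomer comparison
# ---------------------------------------------------------------------------


@dataclass
class OligomerComparison:
    """Per-scheme stability summary and the stability-based intermediate list."""

    table: pd.DataFrame
    candidate_intermediates: list[str]


def _scheme_size(label: str) -> int:
    m, n = (int(x) for x in label.split("-"))
    return m + n


def compare_oligomers(
    schemes: Sequence[str] = SCHEME_LABELS,
    geometry: ZipperGeometry | None = None,
    fluctuations: Mapping[str, FluctuationSpec] | FluctuationSpec | None = None,
    rule: StabilityRule = StabilityRule(),
    seed: int = 0,
) -> OligomerComparison:
    """Analyze a synthetic ensemble per oligomer scheme and rank stability.

    ``fluctuations`` may be one spec for all schemes or a per-scheme
    mapping (e.g. to inject strand expulsion into selected schemes).  Each
    scheme gets a deterministic sub-seed derived from ``seed``.
    ``candidate_intermediates`` are the schemes passing the stability rule,
    ordered by size — descriptive only, no kinetic claim.
    """
    geometry = geometry or ZipperGeometry()
    hexamer = build_hexamer_topology(antiparallel=geometry.antiparallel)
    rows = []
    verdicts: dict[str, StabilityVerdict] = {}
    for k, label in enumerate(schemes):
        topo = extract_oligomer(hexamer, label).renumbered()
        if isinstance(fluctuations, Mapping):
            spec = fluctuations.get(label) or FluctuationSpec()
        else:
            spec = fluctuations or FluctuationSpec()
        sub_seed = (seed * 1009 + 7 * k + 1) % (2**31)
        spec = FluctuationSpec(
            per_residue_sigma=spec.per_residue_sigma,
            twist_deg_per_strand=spec.twist_deg_per_strand,
            expelled_strands=spec.expelled_strands,
            sheet_compression=spec.sheet_compression,
            n_frames=spec.n_frames,
            dt_ns=spec.dt_ns,
            seed=sub_seed,
        )
        native = build_ideal_zipper(geometry, topo)
        traj = generate_trajectory(native, spec, topo)
        contacts = mx.detect_native_contacts(native, topo)
        hbonds = mx.detect_hbonds(native, topo)
        rmsd = mx.ca_rmsd(traj)
        verdict = classify_stability(rmsd, rule)
        verdicts[label] = verdict
        qf_trace = mx.qf_series(traj, contacts) if contacts else np.full(traj.n_frames, np.nan)
        mx.interaction_population([traj], contacts)
        mx.interaction_population([traj], hbonds)
        mean_contacts = mx.per_residue_average(contacts, topo.n_strands).mean()
        mean_hbonds = mx.per_residue_average(hbonds, topo.n_strands).mean()
        rows.append(
            {
                "scheme": label,
                "n_strands": topo.n_strands,
                "mean_rmsd": verdict.mean_rmsd,
                "max_rmsd": verdict.max_rmsd,
                "stable": verdict.stable,
                "mean_qf": float(np.nanmean(qf_trace)),
                "per_residue_contacts": float(mean_contacts),
                "per_residue_hbonds": float(mean_hbonds),
            }
        )
    table = pd.DataFrame(rows)
    intermediates = sorted(
        (label for label in schemes if verdicts[label].stable),
        key=_scheme_size,
    )
    return OligomerComparison(table=table, candidate_intermediates=intermediates)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def _fluctuation_from_config(block: Mapping, seed: int) -> FluctuationSpec:
    expelled = {
        int(k): tuple(float(x) for x in v)
        for k, v in (block.get("expelled_strands") or {}).items()
    }
    return FluctuationSpec(
        per_residue_sigma=tuple(
            block.get("per_residue_sigma", FluctuationSpec.per_residue_sigma)
        ),
        twist_deg_per_strand=float(block.get("twist_deg_per_strand", 0.0)),
        expelled_strands=expelled,
        sheet_compression=float(block.get("sheet_compression", 0.0)),
        n_frames=int(block.get("n_frames", 200)),
        dt_ns=float(block.get("dt_ns", 0.1)),
        seed=int(block.get("seed", seed)),
    )


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Run the full analysis described by a config mapping.

    Config keys: ``seed``; ``scheme`` ("m-n", default "3-3");
    ``input_pdb`` (multi-model trajectory; omitted -> synthetic generation
    from the ``geometry`` and ``fluctuations`` blocks); ``cutoffs``
    (``hbond``, ``contact``, ``intersheet_contact``); ``burn_in`` fraction;
    ``stability`` (``threshold``, ``statistic``).

    Writes metrics.csv, rmsf.csv, populations_hbonds.csv,
    populations_contacts.csv, per_residue.csv, verdict.json, topology.json,
    run_log.json and, for synthetic inputs, trajectory.pdb.  Identical
    config + seed produce identical outputs; on failure a FAILED marker
    file is left next to any partial outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "FAILED"
    try:
        result = _run_pipeline_inner(dict(config), out_dir)
    except Exception:
        marker.write_text("pipeline failed; outputs may be partial\n")
        raise
    if marker.exists():
        marker.unlink()
    return result


def _run_pipeline_inner(config: dict, out_dir: Path) -> dict:
    seed = int(config.get("seed", 0))
    scheme = str(config.get("scheme", "3-3"))
    cutoffs = dict(config.get("cutoffs") or {})
    hbond_cutoff = float(cutoffs.get("hbond", mx.HBOND_CUTOFF))
    contact_cutoff = float(cutoffs.get("contact", mx.CONTACT_CUTOFF))
    intersheet_cutoff = cutoffs.get("intersheet_contact")
    intersheet_cutoff = None if intersheet_cutoff is None else float(intersheet_cutoff)
    burn_in = float(config.get("burn_in", 0.0))
    stab = dict(config.get("stability") or {})
    rule = StabilityRule(
        threshold=float(stab.get("threshold", RMSD_INSTABILITY_THRESHOLD)),
        statistic=str(stab.get("statistic", "mean")),
        burn_in=burn_in,
    )

    geometry_block = dict(config.get("geometry") or {})
    geometry = ZipperGeometry(**geometry_block)
    hexamer = build_hexamer_topology(antiparallel=geometry.antiparallel)
    topology = extract_oligomer(
        hexamer, scheme, selection=config.get("strand_selection")
    ).renumbered()

    if config.get("input_pdb"):
        path = Path(config["input_pdb"])
        if not path.exists():
            raise FileNotFoundError(f"input trajectory not found: {path}")
        loaded = read_pdb(path)
        if not isinstance(loaded, Trajectory):
            raise ValueError(f"{path} holds a single model, not a trajectory")
        traj = loaded
        traj.topology = topology
        native = traj.structure
    else:
        spec = _fluctuation_from_config(dict(config.get("fluctuations") or {}), seed)
        native = build_ideal_zipper(geometry, topology)
        traj = generate_trajectory(native, spec, topology)
        write_pdb(out_dir / "trajectory.pdb", traj)

    logger.info("analyzing %s scheme, %d frames", scheme, traj.n_frames)
    contacts = mx.detect_native_contacts(
        native, topology, cutoff=contact_cutoff, intersheet_cutoff=intersheet_cutoff
    )
    hbonds = mx.detect_hbonds(native, topology, cutoff=hbond_cutoff)
    series = mx.compute_metric_series(
        traj, topology, reference=native, native_contacts=contacts
    )
    verdict = classify_stability(series.rmsd, rule)
    contact_pops = mx.interaction_population([traj], contacts, burn_in=burn_in)
    hbond_pops = mx.interaction_population([traj], hbonds, burn_in=burn_in)
    per_residue = pd.DataFrame(
        {
            "residue_position": np.arange(1, 7),
            "contacts": mx.per_residue_average(contacts, topology.n_strands),
            "hbonds": mx.per_residue_average(hbonds, topology.n_strands),
        }
    )

    series.to_frame().to_csv(out_dir / "metrics.csv", index=False)
    series.rmsf.to_csv(out_dir / "rmsf.csv", index=False)
    contact_pops.to_csv(out_dir / "populations_contacts.csv", index=False)
    hbond_pops.to_csv(out_dir / "populations_hbonds.csv", index=False)
    per_residue.to_csv(out_dir / "per_residue.csv", index=False)
    (out_dir / "verdict.json").write_text(json.dumps(asdict(verdict), indent=1))
    (out_dir / "topology.json").write_text(topology.to_json())
    run_log = {
        "config": _jsonable(config),
        "seed": seed,
        "scheme": scheme,
        "cutoffs": {
            "hbond": hbond_cutoff,
            "contact": contact_cutoff,
            "intersheet_contact": intersheet_cutoff,
        },
        "burn_in": burn_in,
        "n_frames": int(traj.n_frames),
        "n_native_contacts": len(contacts),
        "n_hbonds": len(hbonds),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=1))
    return {
        "verdict": verdict,
        "series": series,
        "contacts": contacts,
        "hbonds": hbonds,
        "contact_populations": contact_pops,
        "hbond_populations": hbond_pops,
        "per_residue": per_residue,
        "topology": topology,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
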