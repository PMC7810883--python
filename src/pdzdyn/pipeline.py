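"""Variant-comparison workflow: wt vs phospho/mimetic trajectory sets.

One config file (YAML or JSON) drives the whole comparison: per-variant
trajectory/topology paths, the analysis blocks to run (RMSF, contacts
with a pair list, secondary-structure regions, loop clustering, CSP) and
every threshold.  Outputs are plain CSV/JSON tables plus a run log that
echoes every threshold and decision, so a result can always be traced to
its criteria.  The pipeline is a pure function of (inputs, config, seed):
rerunning on identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    OccurrenceCriteria,
    align_trajectory,
    cluster_conformations,
    combine_replicas,
    compute_rmsf,
    csp_profile,
    delta_rmsf,
    detect_folding_events,
    helix_fraction,
    occurrence_ratio,
    occurrence_decision,
    contact_states,
    distance_series,
    read_peaklist,
    read_topology,
    read_trajectory,
    rank_affinity,
    ss_timeseries,
)

__all__ = ["RunConfig", "StageError", "ConfigError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    variants: dict                 # label -> {"topology": path, "trajectories": [paths]}
    output_dir: str
    wt_label: str = "wt"
    equilibration_fraction: float = 0.1
    stride: int = 1
    seed: int = 0
    fit_selection: str = "name CA"
    rmsf: bool = True
    contacts: dict | None = None   # {"pairs": [{"label","a","b"}], "cutoff_nm", ...}
    ss_regions: dict | None = None  # {"alpha1": [285, 292], ...}
    clustering: dict | None = None  # {"selection": ..., "cutoff_nm": ...}
    csp: dict | None = None        # {"series": {label: path}, "reporters": [...]}

    def __post_init__(self):
        if not self.variants:
            raise ConfigError("config lists no variants")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ConfigError("equilibration_fraction must be in [0, 1)")
        for label, entry in self.variants.items():
            for key in ("topology", "trajectories"):
                if key not in entry:
                    raise ConfigError(f"variant {label!r} lacks {key!r}")
            paths = [entry["topology"], *entry["trajectories"]]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigError(f"variant {label!r}: path does not exist: {p}")
        if self.csp:
            for label, p in self.csp.get("series", {}).items():
                if not Path(p).exists():
                    raise ConfigError(f"csp series {label!r}: path does not exist: {p}")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _criteria(block: dict) -> OccurrenceCriteria:
    return OccurrenceCriteria(
        distance_cutoff_nm=block.get("cutoff_nm", 1.0),
        min_event_ns=block.get("min_event_ns", 20.0),
        min_occupancy=block.get("min_occupancy", 0.25),
        gap_tolerance_ns=block.get("gap_tolerance_ns", 0.0),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns a manifest of written outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str):
        log.append(msg)

    note(f"seed={config.seed} stride={config.stride} "
         f"equilibration_fraction={config.equilibration_fraction}")

    written: dict = {"log": str(out / "run_log.txt")}
    replicas: dict[str, list] = {}
    profiles: dict[str, object] = {}

    for label, entry in config.variants.items():
        stage = f"load[{label}]"
        try:
            top, _ = read_topology(entry["topology"])
            trajs = []
            for p in entry["trajectories"]:
                traj = read_trajectory(p, top)
                skip = int(config.equilibration_fraction * traj.n_frames)
                traj = traj.slice_frames(slice(skip, None, config.stride))
                trajs.append(traj)
            replicas[label] = trajs
            note(f"{stage}: {len(trajs)} replica(s), "
                 f"{trajs[0].n_frames} frames after discard")
        except Exception as exc:
            raise StageError(f"stage {stage} failed on {entry}: {exc}") from exc

    if config.rmsf:
        for label, trajs in replicas.items():
            stage = f"rmsf[{label}]"
            try:
                per_rep = [compute_rmsf(align_trajectory(t, 0, config.fit_selection))
                           for t in trajs]
                prof = combine_replicas(per_rep) if len(per_rep) >= 2 else per_rep[0]
                profiles[label] = prof
                df = pd.DataFrame({"residue_number": prof.residue_numbers,
                                   "rmsf_nm": prof.rmsf_nm,
                                   "std_nm": prof.std_nm if prof.std_nm is not None
                                   else np.zeros_like(prof.rmsf_nm)})
                path = out / f"rmsf_{label}.csv"
                df.to_csv(path, index=False, float_format="%.6f")
                written.setdefault("rmsf", {})[label] = str(path)
            except Exception as exc:
                raise StageError(f"stage {stage} failed: {exc}") from exc
        wt = config.wt_label
        others = [l for l in profiles if l != wt]
        if wt in profiles and others:
            for label in others:
                d = delta_rmsf(profiles[label], profiles[wt], label)
                path = out / f"delta_rmsf_{label}.csv"
                pd.DataFrame({"residue_number": d.residue_numbers,
                              "delta_nm": d.delta_nm}).to_csv(
                    path, index=False, float_format="%.6f")
                written.setdefault("delta_rmsf", {})[label] = str(path)
        else:
            note("delta_rmsf: skipped (wild type only, nothing to compare)")

    if config.contacts:
        crit = _criteria(config.contacts)
        note(f"contacts: cutoff={crit.distance_cutoff_nm} nm "
             f"min_event={crit.min_event_ns} ns min_occupancy>{crit.min_occupancy} "
             f"gap_tolerance={crit.gap_tolerance_ns} ns")
        table = {}
        for label, trajs in replicas.items():
            table[label] = {}
            for pair in config.contacts["pairs"]:
                stage = f"contacts[{label}:{pair.get('label', '?')}]"
                try:
                    decisions, series_paths = [], []
                    for k, traj in enumerate(trajs):
                        s = distance_series(traj, pair["a"], pair["b"],
                                            pair_label=pair.get("label"))
                        st = contact_states(s, crit)
                        decisions.append(occurrence_decision(st, s.times_ns, crit))
                        sp = out / f"dist_{label}_{pair.get('label', 'pair')}_{k}.csv"
                        pd.DataFrame({"time_ns": s.times_ns,
                                      "distance_nm": s.distances_nm}).to_csv(
                            sp, index=False, float_format="%.5f")
                        series_paths.append(sp.name)
                    result = occurrence_ratio(decisions)
                    table[label][pair.get("label", f"{pair['a']}--{pair['b']}")] = {
                        "ratio": result.ratio,
                        "per_replica": result.per_replica,
                        "series": series_paths,
                    }
                except Exception as exc:
                    raise StageError(f"stage {stage} failed: {exc}") from exc
        path = out / "occurrence.json"
        with open(path, "w") as fh:
            json.dump({"criteria": {"cutoff_nm": crit.distance_cutoff_nm,
                                    "min_event_ns": crit.min_event_ns,
                                    "min_occupancy": crit.min_occupancy,
                                    "gap_tolerance_ns": crit.gap_tolerance_ns},
                       "table": table}, fh, indent=2, sort_keys=True)
        written["occurrence"] = str(path)

    if config.ss_regions:
        for label, trajs in replicas.items():
            stage = f"ss[{label}]"
            try:
                rows = []
                for k, traj in enumerate(trajs):
                    ss = ss_timeseries(traj)
                    for region_name, (lo, hi) in config.ss_regions.items():
                        frac = helix_fraction(ss, (lo, hi))
                        events = detect_folding_events(frac, ss.times_ns,
                                                       region=(lo, hi))
                        for t, fr in zip(ss.times_ns, frac):
                            rows.append((k, region_name, t, fr))
                        note(f"ss[{label}:{region_name}:rep{k}]: "
                             f"{len(events)} folding event(s)")
                path = out / f"ss_fraction_{label}.csv"
                pd.DataFrame(rows, columns=["replica", "region", "time_ns",
                                            "helix_fraction"]).to_csv(
                    path, index=False, float_format="%.4f")
                written.setdefault("ss", {})[label] = str(path)
            except Exception as exc:
                raise StageError(f"stage {stage} failed: {exc}") from exc

    if config.clustering:
        for label, trajs in replicas.items():
            stage = f"cluster[{label}]"
            try:
                summary = []
                for k, traj in enumerate(trajs):
                    al = align_trajectory(traj, 0, config.fit_selection)
                    res = cluster_conformations(
                        al, config.clustering["selection"],
                        config.clustering.get("cutoff_nm", 0.15))
                    sizes = np.bincount(res.frame_labels).tolist()
                    summary.append({"replica": k, "n_clusters": res.n_clusters,
                                    "sizes": sizes,
                                    "medoid_frames": res.medoid_frames.tolist()})
                path = out / f"clusters_{label}.json"
                with open(path, "w") as fh:
                    json.dump(summary, fh, indent=2)
                written.setdefault("clusters", {})[label] = str(path)
            except Exception as exc:
                raise StageError(f"stage {stage} failed: {exc}") from exc

    if config.csp:
        stage = "csp"
        try:
            series = {label: read_peaklist(p)
                      for label, p in config.csp["series"].items()}
            reporters = config.csp.get("reporters", [260, 261, 279, 285])
            rows = []
            for label, s in series.items():
                for res in reporters:
                    rec = csp_profile(s, res)
                    for ratio, val in zip(rec.ligand_ratios, rec.delta_obs_ppm):
                        rows.append((label, res, ratio, val))
            path = out / "csp.csv"
            pd.DataFrame(rows, columns=["variant", "residue", "ligand_ratio",
                                        "delta_obs_ppm"]).to_csv(
                path, index=False, float_format="%.6f")
            written["csp"] = str(path)
            if len(series) >= 2:
                ranked = rank_affinity(list(series.values()), reporters)
                path = out / "affinity_ranking.json"
                with open(path, "w") as fh:
                    json.dump(ranked, fh, indent=2)
                written["affinity_ranking"] = str(path)
                note("affinity order: " + " > ".join(r["variant"] for r in ranked))
        except Exception as exc:
            raise StageError(f"stage {stage} failed: {exc}") from exc

    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log) + "\n")

    def _relative(obj):
        if isinstance(obj, dict):
            return {k: _relative(v) for k, v in obj.items()}
        return Path(obj).name

    # JSON artifacts carry paths relative to the output directory so that
    # identical runs into different directories stay byte-identical
    with open(out / "outputs.json", "w") as fh:
        json.dump(_relative(written), fh, indent=2, sort_keys=True)
    return written
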