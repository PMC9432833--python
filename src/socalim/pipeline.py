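"""Configuration-driven end-to-end runs.

``run`` executes behavior -> (extraction) -> classify -> tuning -> kinetics
-> network on a synthetic session (or a supplied dF/F file) and writes the
report tables.  A single top-level seed fans out to per-module child seeds
via ``numpy.random.SeedSequence(seed).spawn``, in the fixed order
(behavior, dff, video, classify), so any module can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_population, signal_behavior_correlation
from .core import SOCIAL_EVENTS, DffMatrix
from .io import (
    read_dff_h5,
    write_dff_h5,
    write_epochs_csv,
    write_session_csv,
    write_trajectory_csv,
)
from .kinetics import kinetic_summary
from .network import correlation_network, signed_clustering, splice_by_state
from .synthetic import SimulationConfig, simulate_behavior, simulate_dff
from .tuning import compute_tuning, ean_counts


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dff_path: str | None = None        # skip simulation of dF/F, load from HDF5
    seed: int = 0
    k: int = 1000
    upper_pct: float = 99.17
    lower_pct: float = 0.83
    beta: float = 0.5
    alpha: float = 1.0
    kinetics_window_s: float = 4.0
    network_state: str = "social"      # "social" or an event type
    outdir: str = "socalim_run"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulation", {})
        if "stage_durations" in sim:
            sim["stage_durations"] = tuple(sim["stage_durations"])
        if "epoch_duration_range" in sim:
            sim["epoch_duration_range"] = tuple(sim["epoch_duration_range"])
        if "arena_size" in sim:
            sim["arena_size"] = tuple(sim["arena_size"])
        return cls(simulation=SimulationConfig(**sim), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def child_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-module child seeds from the top-level seed."""
    return [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n)]


def run(config: RunConfig) -> dict:
    """Execute the full chain and write report tables under ``outdir``.

    Returns a dict with the in-memory results (session, dff, labels,
    profiles, kinetics, network) plus the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)

    try:
        session = simulate_behavior(config.simulation, seed=seeds[0])
    except ValueError as exc:
        raise RuntimeError(f"behavior stage failed: {exc}") from exc

    truth = None
    if config.dff_path is not None:
        p = Path(config.dff_path)
        if not p.exists():
            raise FileNotFoundError(f"dF/F input not found: {p}")
        dff = read_dff_h5(p)
    else:
        dff, truth = simulate_dff(config.simulation, session, seed=seeds[1])

    write_session_csv(session, out / "session.csv")
    write_epochs_csv(session.epochs, out / "epochs.csv")
    if session.trajectory is not None:
        write_trajectory_csv(session.trajectory, out / "trajectory.csv")
    write_dff_h5(dff, out / "dff.h5", truth=truth)

    # --- classify against the sociability-stage social vector
    sl = session.stage_slices["sociability"]
    b_m = session.vectors["mouse"][sl]
    dff_stage = DffMatrix(C=dff.C[:, sl], t=dff.t[sl], rate=dff.rate,
                          neuron_ids=dff.neuron_ids)
    rng = np.random.default_rng(seeds[3])
    try:
        results = classify_population(b_m, dff_stage, k=config.k,
                                      upper_pct=config.upper_pct,
                                      lower_pct=config.lower_pct, rng=rng)
    except ValueError as exc:
        raise RuntimeError(f"classify stage failed: {exc}") from exc
    labels_df = pd.DataFrame([
        {"neuron_id": r.neuron_id, "S": r.s, "threshold_lo": r.threshold_lo,
         "threshold_hi": r.threshold_hi, "label": r.label}
        for r in results
    ])
    labels_df.to_csv(out / "labels.csv", index=False)

    # --- tuning
    try:
        profiles = compute_tuning(dff, session, beta=config.beta)
    except ValueError as exc:
        raise RuntimeError(f"tuning stage failed: {exc}") from exc
    tuning_df = pd.DataFrame([
        {"neuron_id": p.neuron_id,
         **{f"c_{ev}": p.c_e[ev] for ev in p.c_e},
         **{name: on for name, on in p.flags.items()},
         "preferred": p.preferred}
        for p in profiles
    ])
    tuning_df.to_csv(out / "tuning.csv", index=False)

    # --- kinetics on social epochs
    social_epochs = [e for e in session.epochs if e.event in SOCIAL_EVENTS]
    kin_rows = []
    for i in range(dff.n_neurons):
        ks = kinetic_summary(dff.C[i], social_epochs, dff.rate,
                             window_s=config.kinetics_window_s)
        kin_rows.append({"neuron_id": int(dff.neuron_ids[i]), "P_up": ks.p_up,
                         "rise_time_s": ks.rise_time_s, "amplitude": ks.amplitude,
                         "n_activated": ks.n_activated,
                         "n_nonactivated": ks.n_nonactivated,
                         "n_discarded": ks.n_discarded})
    kin_df = pd.DataFrame(kin_rows)
    kin_df.to_csv(out / "kinetics.csv", index=False)

    # --- network on the requested state
    if config.network_state == "social":
        b_state = session.social_vector()
    else:
        b_state = session.vectors[config.network_state]
    try:
        spliced = splice_by_state(dff.C, b_state)
        W, flagged = correlation_network(spliced)
        clust = signed_clustering(W)
    except ValueError as exc:
        raise RuntimeError(f"network stage failed: {exc}") from exc
    pd.DataFrame(W).to_csv(out / "correlation_matrix.csv", index=False)
    pd.DataFrame({"neuron_id": np.asarray(dff.neuron_ids),
                  "C_pos": clust.c_pos, "C_neg": clust.c_neg,
                  "zero_variance": flagged}).to_csv(out / "network_nodes.csv",
                                                    index=False)

    # --- report tables
    n = len(results)
    counts = labels_df["label"].value_counts().to_dict()
    ratio_rows = [{"label": lab, "count": counts.get(lab, 0),
                   "fraction": counts.get(lab, 0) / n if n else float("nan")}
                  for lab in ("SAN", "SIN", "Other")]
    for name, cnt in ean_counts(profiles).items():
        ratio_rows.append({"label": name, "count": cnt,
                           "fraction": cnt / n if n else float("nan")})
    pd.DataFrame(ratio_rows).to_csv(out / "ensemble_ratios.csv", index=False)

    manifest = {
        "socalim_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "child_seeds": seeds,
        "config_hash": config.config_hash(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "signal_behavior_correlation": signal_behavior_correlation(results),
        "mean_clustering_pos": clust.mean_pos,
        "mean_clustering_neg": clust.mean_neg,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"session": session, "dff": dff, "truth": truth, "labels": results,
            "profiles": profiles, "kinetics": kin_df, "W": W,
            "clustering": clust, "manifest": manifest}
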