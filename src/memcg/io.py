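"""Pipeline driver and tabular/JSON writers.

``run_pipeline`` ties the stages together: read end-state structures,
coarse-grain, residue-match, morph, and profile — writing a TSV profile, a
JSON summary, and a YAML config snapshot. Outputs are byte-deterministic
for identical inputs, configuration, and seeds.
"""

from __future__ import annotations

import json
import logging
import os

from .config import RunConfig, config_hash, dump_run_config, load_run_config
from .pathway import PathwayProfile, extract_barrier, interpolate, profile
from .structures import coarse_grain, read_pdb

log = logging.getLogger("memcg")


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_profile_tsv(prof: PathwayProfile, path):
    if len(prof) == 0:
        raise ValueError("empty profile")
    n = len(prof)
    with open(path, "w") as fh:
        fh.write("frame_index\tt\tlabel\tg_mean\tg_sd\n")
        for k in range(n):
            t = k / (n - 1) if n > 1 else 0.0
            label = prof.labels[k] if k < len(prof.labels) else ""
            fh.write(f"{k}\t{_fmt(t)}\t{label}\t{_fmt(prof.g[k])}\t"
                     f"{_fmt(prof.g_sd[k])}\n")


def write_summary_json(prof: PathwayProfile, path, legs=None,
                       cfg_hash: str = ""):
    if len(prof) == 0:
        raise ValueError("empty profile")
    payload = {
        "barrier": prof.barrier,
        "barrier_frame_index": prof.barrier_frame_index,
        "reaction_dg": prof.reaction_dg,
        "pH": prof.pH,
        "seeds": list(prof.seeds),
        "n_frames": len(prof),
        "legs": legs or [],
        "config_hash": cfg_hash,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_pipeline(end_state_paths, config_path=None, out_dir=".",
                 run_config: RunConfig | None = None) -> int:
    """End-to-end: structures -> CG -> morph -> per-frame energies ->
    profile files. Returns 0 on success; failures raise with a message
    naming the stage."""
    paths = list(end_state_paths)
    if len(paths) < 2:
        raise ValueError("need at least two end-state structures")
    cfg = run_config or load_run_config(config_path)
    chash = config_hash(cfg)
    log.info("run config %s seeds %s", chash, list(cfg.pathway.seeds))

    states = []
    for p in paths:
        try:
            model = read_pdb(p)
            states.append(coarse_grain(model, cfg.energy,
                                       label=os.path.basename(str(p))))
        except Exception as exc:
            raise RuntimeError(f"read/coarse-grain stage failed for {p}: "
                               f"{exc}") from exc

    frames = []
    leg_bounds = []
    for i in range(len(states) - 1):
        try:
            leg = interpolate(states[i], states[i + 1],
                              cfg.pathway.n_frames)
        except Exception as exc:
            raise RuntimeError(
                f"morphing stage failed for leg {i}: {exc}") from exc
        start = len(frames) - 1 if frames else 0
        if frames:
            leg = leg[1:]  # shared junction frame
        frames.extend(leg)
        leg_bounds.append((start, len(frames) - 1))

    try:
        prof = profile(
            frames, cfg.pathway.pH, cfg.energy, cfg.grid, mc=cfg.mc,
            seeds=cfg.pathway.seeds, relax_steps=cfg.pathway.relax_steps,
            relax_step_size=cfg.pathway.relax_step_size)
    except Exception as exc:
        raise RuntimeError(f"profiling stage failed: {exc}") from exc

    legs = []
    for i, (a, b) in enumerate(leg_bounds):
        barrier, idx, dg = extract_barrier(prof.g[a:b + 1])
        legs.append({
            "leg": i, "start_frame": a, "end_frame": b,
            "barrier": barrier, "barrier_frame_index": a + idx,
            "reaction_dg": dg,
        })

    os.makedirs(out_dir, exist_ok=True)
    write_profile_tsv(prof, os.path.join(out_dir, "profile.tsv"))
    write_summary_json(prof, os.path.join(out_dir, "summary.json"),
                       legs=legs, cfg_hash=chash)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        fh.write(dump_run_config(cfg))
    log.info("wrote profile.tsv, summary.json, config.yaml to %s", out_dir)
    return 0
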