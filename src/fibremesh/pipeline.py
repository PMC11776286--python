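"""End-to-end orchestration: layout → network → simulate → stress → render
→ quantify, with deterministic seeding and a checksummed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, elastostatics, geometry, metrics, netgen, synthmicro
from .config import RunConfig, stage_seeds

__all__ = ["run_pipeline", "compare_patterns", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _layout_from_config(config: RunConfig) -> geometry.ClusterLayout:
    seeds = stage_seeds(config.seed)
    pattern = config.pattern
    if pattern.kind == "random_array":
        pattern = dataclasses.replace(pattern, rng_seed=seeds["pattern"])
    return geometry.make_layout(pattern)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest (path → sha256).

    Artifacts: layout CSV/JSON, network JSON, trajectory (extended XYZ) and
    per-frame CSV, stress-component CSVs with a JSON header plus ridge and
    alignment tables, a rendered TIFF/PNG of the final state, a long-format
    metrics CSV, a log, and ``manifest.json``. A fixed master seed gives a
    bitwise-identical artifact set. Stage failures are recorded in the log
    and re-raised as :class:`PipelineError`; partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.txt"
    log_lines: list[str] = []
    seeds = stage_seeds(config.seed)
    run_id = f"{config.pattern.kind}-seed{config.seed}"

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")
        log_path.write_text("\n".join(log_lines) + "\n")

    def fail(stage: str, exc: BaseException) -> PipelineError:
        log(stage, f"FAILED: {exc}")
        return PipelineError(stage, exc)

    # --- layout
    try:
        layout = _layout_from_config(config)
        geometry.write_layout(layout, outdir / "layout.csv", spec=config.pattern)
        graph = geometry.pair_graph(layout)
        log("layout", f"{layout.n_clusters} clusters, kind={layout.kind}")
    except Exception as exc:
        raise fail("layout", exc)

    # --- network
    try:
        nspec = dataclasses.replace(config.network, rng_seed=seeds["network"])
        net = netgen.build_network(nspec)
        embedded = netgen.embed_clusters(net, layout, config.cluster)
        netgen.write_network(embedded, outdir / "network.json")
        log("netgen", f"{embedded.n_nodes} nodes, {embedded.n_bonds} bonds")
    except Exception as exc:
        raise fail("netgen", exc)

    # --- simulate
    try:
        lparams = dataclasses.replace(config.langevin, rng_seed=seeds["langevin"])
        traj = dynamics.run(
            embedded,
            schedule=config.schedule,
            rule=config.remodel,
            params=lparams,
            potential=config.potential,
        )
        traj.write_xyz(outdir / "trajectory.xyz")
        traj.metrics_frame().to_csv(outdir / "frames.csv", index=False)
        log("simulate",
            f"{len(traj.frames)} frames, {traj.final['remodel_events']} remodel events, "
            f"final energy {traj.final['energy']:.6g}")
    except Exception as exc:
        raise fail("simulate", exc)

    # --- stress field
    try:
        field = elastostatics.solve(layout, config.elastic)
        header = {
            "x": field.x.tolist(), "y": field.y.tolist(),
            "params": dataclasses.asdict(field.params),
        }
        (outdir / "stress_header.json").write_text(json.dumps(header, sort_keys=True))
        for name in ("sxx", "syy", "sxy"):
            np.savetxt(outdir / f"stress_{name}.csv", getattr(field, name), delimiter=",")
        ridge = elastostatics.ridge_profile(field, graph)
        ridge.to_csv(outdir / "ridge.csv", index=False)
        align = elastostatics.principal_alignment(field, graph)
        align.to_csv(outdir / "alignment.csv", index=False)
        log("stress", f"max tau {np.nanmax(field.tau_max):.6g}")
    except Exception as exc:
        raise fail("stress", exc)

    # --- render
    try:
        rspec = dataclasses.replace(config.render, rng_seed=seeds["render"])
        image = synthmicro.render(embedded, positions=traj.final["positions"], spec=rspec)
        synthmicro.write_image(image, outdir / "final.tif", spec=rspec)
        synthmicro.write_image(
            np.clip(image // max(1, (image.max() // 255) or 1), 0, 255).astype(np.uint8),
            outdir / "final.png",
        )
        log("render", f"image {image.shape}, dtype {image.dtype}")
    except Exception as exc:
        raise fail("render", exc)

    # --- quantify
    try:
        rows = []
        score0 = metrics.bundle_scores(traj.initial["positions"], embedded, graph)
        score1 = metrics.bundle_scores(traj.final["positions"], embedded, graph)
        for (_, r0), (_, r1) in zip(score0.iterrows(), score1.iterrows()):
            for step_label, r in ((traj.initial["step"], r0), (traj.final["step"], r1)):
                rows.append(
                    {"run_id": run_id, "step": step_label,
                     "edge_id": f"{int(r['i'])}-{int(r['j'])}",
                     "distance": r["distance"], "kind": r["kind"],
                     "bundle_score": r["score"], "fl_ratio": np.nan,
                     "remaining_area_pct": np.nan}
                )
        # fluorescence ratio across the shortest (side) edge of the image
        side = graph.side_edges().iloc[0]
        i, j = int(side["i"]), int(side["j"])
        centers_sim = embedded.cluster_centers
        px_per_unit = embedded.spec.um_per_unit / rspec.pixel_size_um
        mid = 0.5 * (centers_sim[i] + centers_sim[j]) * px_per_unit
        edge_vec = centers_sim[j] - centers_sim[i]
        perp_deg = np.degrees(np.arctan2(edge_vec[1], edge_vec[0])) + 90.0
        radius_px = embedded.cluster_radius * px_per_unit
        roi = metrics.RectROI(center=(mid[0], mid[1]),
                              length=max(15.0, 6.0 * radius_px),
                              width=max(3.0, radius_px), angle_deg=perp_deg)
        prof = metrics.fl_ratio(image, roi)
        rows.append({"run_id": run_id, "step": traj.final["step"],
                     "edge_id": f"{i}-{j}", "distance": side["distance"],
                     "kind": "side", "bundle_score": np.nan,
                     "fl_ratio": prof.ratio, "remaining_area_pct": np.nan})
        # area stability of the pattern outline (far-side cluster boundary points)
        if layout.n_clusters >= 3:
            centroid = centers_sim.mean(axis=0)
            polys = []
            for fr in traj.frames:
                rel = centers_sim - centroid
                norm = np.hypot(rel[:, 0], rel[:, 1])
                unit = rel / np.where(norm > 0, norm, 1.0)[:, None]
                order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
                polys.append((centers_sim + fr["radii"][:, None] * unit)[order])
            trace = metrics.area_trace(polys)
            for fr, pct in zip(traj.frames, trace.remaining_percent):
                rows.append({"run_id": run_id, "step": fr["step"], "edge_id": "",
                             "distance": np.nan, "kind": "pattern",
                             "bundle_score": np.nan, "fl_ratio": np.nan,
                             "remaining_area_pct": pct})
        pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)
        log("quantify", f"{len(rows)} metric rows")
    except Exception as exc:
        raise fail("quantify", exc)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "log.txt")
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log("done", "manifest written")
    return manifest


def compare_patterns(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Summarize completed runs into a long-format comparison table.

    One row per (run, edge kind) with the mean final bundle score, plus the
    pattern's final remaining-area percentage where recorded, and a
    ``sides_exceed_diagonals`` flag per run. Missing runs are listed in the
    raised error.
    """
    missing = [str(d) for d in run_dirs if not (Path(d) / "metrics.csv").exists()]
    if missing:
        raise FileNotFoundError(f"missing runs (no metrics.csv): {missing}")
    rows = []
    for d in run_dirs:
        df = pd.read_csv(Path(d) / "metrics.csv")
        scores = df.dropna(subset=["bundle_score"])
        if scores.empty:
            continue
        final_step = scores["step"].max()
        final = scores[scores["step"] == final_step]
        by_kind = final.groupby("kind")["bundle_score"].mean()
        area = df.dropna(subset=["remaining_area_pct"])
        area_pct = area["remaining_area_pct"].iloc[-1] if not area.empty else np.nan
        side_mean = by_kind.get("side", np.nan)
        diag_mean = by_kind.get("diagonal", np.nan)
        for kind, val in by_kind.items():
            rows.append(
                {"run": str(d), "run_id": df["run_id"].iloc[0], "edge_kind": kind,
                 "mean_bundle_score": val, "remaining_area_pct": area_pct,
                 "sides_exceed_diagonals": bool(side_mean > diag_mean)
                 if np.isfinite(side_mean) and np.isfinite(diag_mean) else np.nan}
            )
    return pd.DataFrame(
        rows, columns=["run", "run_id", "edge_kind", "mean_bundle_score",
                       "remaining_area_pct", "sides_exceed_diagonals"]
    )
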