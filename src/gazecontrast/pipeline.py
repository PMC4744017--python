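"""End-to-end orchestration: simulate -> behavior -> AOI -> maps -> profiles.

A single YAML (or dict) configuration drives every stage; every threshold
the analyses use (per-tail alpha for spatial and profile maps, FDR q, kernel
sigma, iteration count) is explicit configuration echoed into the output
manifest together with SHA-256 hashes of every data product, so a re-run
with the same config and seed is byte-identical and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aoi import contrasts_frame, default_contrasts, planned_contrasts, relative_frequencies
from .behavior import summarize_behavior
from .density import GridSpec, profile
from .model import Dataset, RACES
from .permutation import (
    PermutationConfig,
    face_region_mask,
    fdr_correct,
    build_contrast_tokens,
    permutation_maps,
    threshold_pmap,
)
from .synth import GeneratorParams, generate_dataset
from .io import write_aois, write_fixations

log = logging.getLogger("gazecontrast")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    generator: dict = field(default_factory=dict)
    grid: dict = field(
        default_factory=lambda: {
            "width": 64,
            "height": 64,
            "pixel_size": 0.25,
            "origin": (-1.5, -0.5),
        }
    )
    sigma: float = 0.3
    contrasts: list = field(
        default_factory=lambda: [["caucasian", "african"], ["caucasian", "chinese"]]
    )
    n_iter: int = 2000
    alpha: float = 0.01  # per-tail, spatial maps (two-tailed 0.02)
    profile_alpha: float = 0.025  # per-tail, profile maps (two-tailed 0.05)
    q: float = 0.05
    by_start_position: bool = False

    def validate(self) -> None:
        for pair in self.contrasts:
            for race in pair:
                if race not in RACES:
                    raise ValueError(f"undefined race label {race!r} in contrasts")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def grid_spec(self) -> GridSpec:
        g = dict(self.grid)
        g["origin"] = tuple(g.get("origin", (0.0, 0.0)))
        return GridSpec(**g)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _save_array(path: Path, arr: np.ndarray, sidecar: dict) -> list[Path]:
    """Flat binary array plus JSON sidecar describing shape/dtype/metadata."""
    arr = np.ascontiguousarray(arr)
    path.write_bytes(arr.tobytes())
    meta = dict(sidecar)
    meta.update({"shape": list(arr.shape), "dtype": str(arr.dtype)})
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n", encoding="utf-8")
    return [path, side]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json).

    On failure, whatever was produced is moved into a ``quarantine/``
    subdirectory together with the error log, so a partial output tree is
    never mistaken for a complete one.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs: list[Path] = []
    stages: dict[str, list[str]] = {}

    def record(stage: str, paths: list[Path]) -> None:
        outputs.extend(paths)
        stages.setdefault(stage, []).extend(str(p.relative_to(out)) for p in paths)
        log.info("stage %s: %d file(s), %.1fs elapsed", stage, len(paths), time.time() - t0)

    try:
        # 1. simulate
        params = GeneratorParams(seed=cfg.seed, **cfg.generator)
        ds = generate_dataset(params)
        p_fix = write_fixations(ds, out / "fixations.tsv")
        p_aoi = write_aois(ds.layouts, out / "aois.tsv")
        p_echo = out / "params-echo.json"
        p_echo.write_text(
            json.dumps(asdict(params), sort_keys=True, default=list, indent=1) + "\n",
            encoding="utf-8",
        )
        record("simulate", [p_fix, p_aoi, p_echo])

        # 2. behavior
        behav = summarize_behavior(ds, by_start_position=cfg.by_start_position)
        p_behav = out / "behavior_summary.tsv"
        behav.to_csv(p_behav, sep="\t", index=False)
        record("behavior", [p_behav])

        # 3. AOI relative frequencies and planned contrasts
        relfreq = relative_frequencies(ds, phase="study", pool_start=True)
        p_rel = out / "relfreq.tsv"
        relfreq.to_csv(p_rel, sep="\t", index=False)
        contrasts = planned_contrasts(relfreq, default_contrasts())
        p_con = out / "contrasts.tsv"
        contrasts_frame(contrasts).to_csv(p_con, sep="\t", index=False)
        record("aoi", [p_rel, p_con])

        # 4-6. density, permutation and profile inference per contrast
        grid = cfg.grid_spec()
        mask = face_region_mask(grid, ds.layouts)
        for race_a, race_b in cfg.contrasts:
            tag = f"{race_a}_vs_{race_b}"
            tokens = build_contrast_tokens(
                ds, {"race": race_a}, {"race": race_b}, grid, sigma=cfg.sigma
            )
            perm = PermutationConfig(n_iter=cfg.n_iter, seed=cfg.seed)
            maps = permutation_maps(tokens, perm)
            observed = maps.pop("observed")
            record(
                f"density:{tag}",
                _save_array(
                    out / f"difference_{tag}.f64",
                    observed.values,
                    {"kind": "difference_map", "contrast": tag, "sigma": cfg.sigma,
                     "n_fixations": observed.n_fixations},
                ),
            )
            pm = maps["map"]
            unc = threshold_pmap(pm, cfg.alpha)
            fdr = fdr_correct(pm, mask, cfg.q)
            files = _save_array(
                out / f"pvalues_{tag}.f64", pm.p,
                {"kind": "pvalue_map", "contrast": tag, "n_iter": pm.n_iter},
            )
            files += _save_array(
                out / f"sig_uncorrected_{tag}.u8",
                unc.mask.astype(np.uint8),
                {"kind": "significance", "method": "uncorrected", **unc.threshold},
            )
            files += _save_array(
                out / f"sig_fdr_{tag}.u8",
                fdr.mask.astype(np.uint8),
                {"kind": "significance", "method": "fdr", **fdr.threshold},
            )
            record(f"mapstats:{tag}", files)
            prof_files: list[Path] = []
            for axis in ("x_profile", "y_profile"):
                ppm = maps[axis]
                punc = threshold_pmap(ppm, cfg.profile_alpha)
                pfdr = fdr_correct(ppm, None, cfg.q)  # profiles: all pixels
                prof_files += _save_array(
                    out / f"profile_{axis}_{tag}.f64", ppm.p,
                    {"kind": "profile_pvalues", "axis": axis, "contrast": tag,
                     "uncorrected_count": int(punc.mask.sum()),
                     "fdr_count": int(pfdr.mask.sum()), **punc.threshold},
                )
            record(f"profiles:{tag}", prof_files)

        manifest = {
            "config": {**asdict(cfg)},
            "seed": cfg.seed,
            "version": __version__,
            "stages": stages,
            "hashes": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            "elapsed_s": round(time.time() - t0, 2),
        }
        # elapsed time is informational and excluded from determinism checks
        p_manifest = out / "manifest.json"
        stable = {k: v for k, v in manifest.items() if k != "elapsed_s"}
        p_manifest.write_text(
            json.dumps(stable, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        return manifest
    except Exception:
        quarantine = out / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for p in outputs:
            if p.exists():
                shutil.move(str(p), quarantine / p.name)
        import traceback

        (quarantine / "error.log").write_text(traceback.format_exc(), encoding="utf-8")
        raise


def render_figures(manifest_path: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Heatmap and profile figures from a pipeline output directory.

    All maps placed in one figure share a single color normalization (zero to
    the maximum observed density magnitude) so they are directly comparable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out_dir = Path(out_dir) if out_dir else base
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    produced: list[Path] = []
    diff_files = sorted(base.glob("difference_*.f64"))
    if diff_files:
        arrays = {}
        for f in diff_files:
            meta = json.loads(f.with_suffix(".f64.json").read_text(encoding="utf-8"))
            arrays[meta["contrast"]] = np.frombuffer(
                f.read_bytes(), dtype=meta["dtype"]
            ).reshape(meta["shape"])
        vmax = max(np.abs(a).max() for a in arrays.values()) or 1.0
        fig, axes = plt.subplots(1, len(arrays), figsize=(4 * len(arrays), 4))
        axes = np.atleast_1d(axes)
        for ax, (tag, arr) in zip(axes, sorted(arrays.items())):
            im = ax.imshow(arr, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_title(tag)
            ax.set_axis_off()
        fig.colorbar(im, ax=list(axes), shrink=0.8, label="density difference")
        p = out_dir / "difference_maps.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        produced.append(p)
    prof_files = sorted(base.glob("profile_y_profile_*.f64"))
    if prof_files:
        fig, ax = plt.subplots(figsize=(5, 4))
        alpha = None
        for f in prof_files:
            meta = json.loads(f.with_suffix(".f64.json").read_text(encoding="utf-8"))
            p_curve = np.frombuffer(f.read_bytes(), dtype=meta["dtype"]).reshape(
                meta["shape"]
            )
            alpha = meta.get("per_tail_alpha")
            ax.plot(p_curve, label=meta["contrast"])
            sig = p_curve < (alpha or 0.025)
            ax.fill_between(
                np.arange(p_curve.size), 0, 1, where=sig, alpha=0.15, step="mid"
            )
        ax.axhline(alpha or 0.025, color="k", ls=":", lw=0.8)
        ax.set_xlabel("vertical pixel (forehead to chin)")
        ax.set_ylabel("per-tail p")
        ax.legend(fontsize=7)
        p = out_dir / "profile_pvalues.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        produced.append(p)
    return produced
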