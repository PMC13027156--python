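"""Field I/O, run configuration and the end-to-end pipeline driver.

Fields are stored as multi-page TIFF (one page per channel, order: nuclear
marker, target, puncta) with a sidecar JSON recording the channel map, the
nesting metadata and the intensity scale. The sidecar is authoritative; a
``group_specimen_image_experiment`` filename pattern is the fallback for
metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from . import __version__
from .datatypes import FieldImage, FieldMeta

logger = logging.getLogger(__name__)

_CHANNEL_ORDER = ("nuclear", "target", "puncta")
_ATTR = {"nuclear": "nuclear_channel", "target": "target_channel", "puncta": "puncta_channel"}


def sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_field(field_img: FieldImage, path, intensity_scale: float = 255.0) -> Path:
    """Write a field as multi-page float32 TIFF + sidecar JSON channel map."""
    path = Path(path)
    pages, channel_map = [], {}
    for name in _CHANNEL_ORDER:
        ch = getattr(field_img, _ATTR[name])
        if ch is not None:
            channel_map[name] = len(pages)
            pages.append(np.asarray(ch, dtype=np.float32))
    tifffile.imwrite(path, np.stack(pages))
    sidecar = {
        "channel_map": channel_map,
        "meta": field_img.meta.as_dict(),
        "intensity_scale": intensity_scale,
    }
    sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _meta_from_filename(path: Path) -> FieldMeta:
    parts = path.stem.split("_")
    if len(parts) != 4:
        raise ValueError(
            f"cannot parse metadata from {path.name!r}: expected "
            "group_specimen_image_experiment pattern and no sidecar JSON found"
        )
    return FieldMeta(group=parts[0], specimen=parts[1], image=parts[2], experiment=parts[3])


def load_field(path, channel_map: Optional[dict] = None) -> FieldImage:
    """Read a multi-page TIFF field; sidecar JSON is the metadata authority.

    ``channel_map`` maps channel names (nuclear/target/puncta) to page
    indices and overrides the sidecar. Raises on missing pages or shape
    mismatches.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta = None
    sc = sidecar_path(path)
    if sc.exists():
        sidecar = json.loads(sc.read_text())
        meta = FieldMeta(**sidecar.get("meta", {}))
        if channel_map is None:
            channel_map = sidecar["channel_map"]
    if channel_map is None:
        channel_map = {"nuclear": 0}
    if meta is None:
        meta = _meta_from_filename(path)
    if "nuclear" not in channel_map:
        raise ValueError("channel_map must include the nuclear channel")
    kwargs = {}
    for name, page in channel_map.items():
        if name not in _ATTR:
            raise ValueError(f"unknown channel {name!r}")
        if page >= len(pages):
            raise ValueError(
                f"{path.name}: channel {name!r} maps to page {page} but the "
                f"TIFF has {len(pages)} page(s)"
            )
        kwargs[_ATTR[name]] = np.asarray(pages[page], dtype=float)
    return FieldImage(meta=meta, **kwargs)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All stage parameters of one analysis run.

    Defaults are the quantification pipeline's canonical values:
    sigma_nuclear=3.0, min_nucleus=700, pla_floor=80, pla_sigma=1.5,
    min_punctum=25, min_pla_nucleus=3000, lfc_cut=1, fdr_cut=0.01.
    ``group_effects`` maps group label to the simulated effect (true
    enrichment ratio for translocation runs, puncta rate per cell for PLA
    runs); the first-listed control group is the contrast reference.
    """

    kind: str = "translocation"  # translocation | pla
    seed: int = 0
    out_dir: str = "run_out"
    log_level: str = "INFO"
    sigma_nuclear: float = 3.0
    min_nucleus: int = 700
    pla_floor: float = 80.0
    pla_sigma: float = 1.5
    min_punctum: int = 25
    min_pla_nucleus: int = 3000
    control: str = "control"
    lfc_cut: float = 1.0
    fdr_cut: float = 0.01
    group_effects: dict = field(default_factory=lambda: {"control": 1.0, "treated": 1.5})
    n_specimens: int = 3
    n_images: int = 4
    n_experiments: int = 1
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derived_seed(base_seed: int, index: int) -> int:
    """Deterministic per-field child seed below 2**31."""
    state = np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
    return int(state % (2**31))


def simulate_study(config: RunConfig, out_dir: Path) -> list[Path]:
    """Generate and write all fields of a simulated imaging study."""
    from .synthetic import SimConfig, generate_pla_field, generate_translocation_field, pla_config

    paths = []
    idx = 0
    for e in range(config.n_experiments):
        for group, effect in config.group_effects.items():
            for s in range(config.n_specimens):
                for i in range(config.n_images):
                    seed = _derived_seed(config.seed, idx)
                    idx += 1
                    meta = FieldMeta(
                        group=group, specimen=f"{group}-s{s+1}",
                        image=f"i{i+1}", experiment=f"e{e+1}",
                    )
                    if config.kind == "translocation":
                        cfg = SimConfig(
                            seed=seed, nuclear_fraction=1.0,
                            marker_amplitude=100.0,
                            target_amplitude=100.0 * effect,
                            **config.sim_overrides,
                        )
                        field_img, _ = generate_translocation_field(cfg, meta=meta)
                    elif config.kind == "pla":
                        cfg = pla_config(seed=seed, puncta_rate=effect, **config.sim_overrides)
                        field_img, _ = generate_pla_field(cfg, meta=meta)
                    else:
                        raise ValueError(f"unknown study kind {config.kind!r}")
                    name = f"{group}_{meta.specimen}_{meta.image}_{meta.experiment}.tif"
                    paths.append(write_field(field_img, out_dir / name))
    return paths


def run_pipeline(config: RunConfig) -> int:
    """Execute the simulate -> quantify -> model workflow.

    Writes ``fields/`` (TIFF + sidecars), ``results.csv`` (per-image
    indices), ``stats.csv`` (EMMs and contrasts) and ``manifest.json``
    (parameters, seed, software version, outputs) under ``config.out_dir``.
    Returns 0 on success; stage errors propagate with the stage name.
    """
    from .nuclear import quantify_nuclear_batch, records_to_frame
    from .pla import quantify_pla_batch
    from .stats import fit_glmm

    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    fields_dir = out_dir / "fields"
    fields_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run parameters: %s", json.dumps(config.to_dict(), sort_keys=True))

    try:
        field_paths = simulate_study(config, fields_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        fields = [load_field(p) for p in field_paths]
        if config.kind == "translocation":
            records = quantify_nuclear_batch(
                fields, sigma=config.sigma_nuclear, min_area=config.min_nucleus
            )
        else:
            records = quantify_pla_batch(
                fields, floor=config.pla_floor, sigma=config.pla_sigma,
                min_punctum=config.min_punctum, min_nucleus=config.min_pla_nucleus,
            )
        frame = records_to_frame(records)
    except Exception as exc:
        raise RuntimeError(f"stage 'quantify' failed: {exc}") from exc
    results_path = out_dir / "results.csv"
    frame.to_csv(results_path, index=False)

    try:
        result = fit_glmm(frame, control=config.control)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
    stats_path = out_dir / "stats.csv"
    write_stats_csv(result, stats_path)

    manifest = {
        "version": __version__,
        # out_dir is the manifest's own location; excluding it keeps the
        # manifest byte-identical across runs of the same config + seed
        "config": {k: v for k, v in config.to_dict().items() if k != "out_dir"},
        "outputs": {
            "fields": sorted(p.name for p in field_paths),
            "results": results_path.name,
            "stats": stats_path.name,
        },
        "model": result.model,
        "converged": result.converged,
        "fallback": result.fallback,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return 0


def write_stats_csv(result, path) -> None:
    """Tidy CSV of EMMs and contrasts (one row per group; contrast columns
    empty for the control row)."""
    import pandas as pd

    emm = result.emm.copy()
    merged = emm.merge(
        result.contrasts[["group", "ratio", "ratio_lower", "ratio_upper", "p", "p_adj"]],
        on="group", how="left",
    )
    merged["fallback"] = result.fallback
    merged["converged"] = result.converged
    pd.DataFrame(merged).to_csv(path, index=False)
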