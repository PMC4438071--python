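"""Video/frame readers, feature and report writers, configuration.

Conventions, stated once and enforced everywhere:

* pixel indexing is 0-based ``[row=y, col=x]``; t is the last axis of a
  volume;
* a video sample is a directory of same-sized grayscale-convertible frames
  (PNG/PGM/TIFF); frames sorted by lexicographic filename define t order,
  so frame writers zero-pad indices;
* color inputs are reduced to luminance with the Rec. 601 weights
  0.299 R + 0.587 G + 0.114 B;
* feature, label and report files are tab-separated text with headers;
  feature columns are named ``<plane>.<block>.<bin>``.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Callable

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import descriptors as D
from .evaluate import Corpus
from .lbp import BlockGrid, FeatureHistogram
from .preprocess import PyramidConfig, WienerConfig, pyramid_video, temporal_resample, wiener_filter

__all__ = [
    "FRAME_EXTENSIONS",
    "PreprocessConfig",
    "read_video",
    "write_video",
    "read_manifest",
    "write_corpus",
    "read_feature_table",
    "write_feature_table",
    "load_config",
    "extract_features",
    "pyramid_extract_features",
]

FRAME_EXTENSIONS = (".png", ".pgm", ".ppm", ".pnm", ".tif", ".tiff", ".bmp")
_LUMA = np.array([0.299, 0.587, 0.114])


def read_video(path: str | Path) -> np.ndarray:
    """Stack a directory of frames into a float (h, w, l) volume.

    Frames are taken in lexicographic filename order; color frames are
    converted to Rec. 601 luminance.  Raises on an empty directory or on
    mixed frame sizes.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS)
    if not files:
        raise FileNotFoundError(f"no decodable frames in {path}")
    frames = []
    for f in files:
        arr = np.asarray(iio.imread(f), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3] @ _LUMA
        if arr.ndim != 2:
            raise ValueError(f"frame {f} has unexpected shape {arr.shape}")
        if frames and arr.shape != frames[0].shape:
            raise ValueError(
                f"mixed frame sizes in {path}: {frames[0].shape} vs {arr.shape} ({f.name})"
            )
        frames.append(arr)
    return np.stack(frames, axis=2)


def write_video(video: np.ndarray, path: str | Path, fmt: str = "png") -> list[Path]:
    """Write a volume as zero-padded 8-bit grayscale frames; returns paths.

    Intensities must lie in [0, 255]; they are rounded to the nearest
    integer, so integer-valued volumes round-trip exactly.
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3:
        raise ValueError(f"expected (h, w, l) volume, got shape {video.shape}")
    if video.min() < 0 or video.max() > 255:
        raise ValueError("intensities outside [0, 255] cannot be written as 8-bit")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = []
    for t in range(video.shape[2]):
        f = path / f"frame{t:04d}.{fmt}"
        iio.imwrite(f, np.round(video[:, :, t]).astype(np.uint8))
        out.append(f)
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest (TSV: sample_id, path, subject_id, label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "subject_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_ids in manifest: {dups[:5]}")
    return df


def write_corpus(corpus: Corpus, outdir: str | Path) -> Path:
    """Write a corpus as frame directories plus a manifest/labels table.

    Layout: ``<outdir>/videos/<sample_id>/frame%04d.png`` and
    ``<outdir>/labels.tsv`` with columns sample_id, path, subject_id, label.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    rows = []
    for s in corpus.samples:
        if s.video is None:
            raise ValueError(f"sample {s.sample_id} has no video attached")
        vdir = outdir / "videos" / s.sample_id
        write_video(s.video, vdir)
        rows.append(
            {
                "sample_id": s.sample_id,
                "path": str(vdir),
                "subject_id": s.subject_id,
                "label": s.label,
            }
        )
    manifest = outdir / "labels.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing switches for feature extraction.

    ``wiener_apply_to`` chooses where denoising happens for MOP: on every
    frame before averaging ('frames') or on the three mean plane images only
    ('mean_planes'); TOP/SIP always filter frames when enabled.
    ``tim_target_length`` fixes the frame count by linear temporal
    resampling (None disables).
    """

    wiener_enabled: bool = False
    wiener: WienerConfig = dataclasses.field(default_factory=WienerConfig)
    wiener_apply_to: str = "frames"  # or "mean_planes" (MOP only)
    tim_target_length: int | None = None

    def __post_init__(self) -> None:
        if self.wiener_apply_to not in ("frames", "mean_planes"):
            raise ValueError(
                f"wiener_apply_to must be 'frames' or 'mean_planes', "
                f"got {self.wiener_apply_to!r}"
            )


def load_config(path: str | Path) -> dict:
    """Load a key-value config file (YAML; dotted or nested keys).

    Documented keys: wiener.window, wiener.enabled, wiener.apply_to,
    pyramid.levels, pyramid.resize, tim.target_length.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict = {}

    def _flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                _flatten(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            flat[prefix] = obj

    _flatten("", raw)
    return flat


def preprocess_config_from_dict(cfg: dict) -> PreprocessConfig:
    window = cfg.get("wiener.window", (3, 3))
    if isinstance(window, (list, tuple)):
        window = tuple(int(v) for v in window)
    else:
        window = (int(window), int(window))
    target = cfg.get("tim.target_length")
    return PreprocessConfig(
        wiener_enabled=bool(cfg.get("wiener.enabled", False)),
        wiener=WienerConfig(window=window),
        wiener_apply_to=str(cfg.get("wiener.apply_to", "frames")),
        tim_target_length=None if target is None else int(target),
    )


def _filter_frames(video: np.ndarray, cfg: WienerConfig) -> np.ndarray:
    out = np.empty_like(video, dtype=float)
    for t in range(video.shape[2]):
        out[:, :, t] = wiener_filter(video[:, :, t], cfg)
    return out


def _descriptor_fn(
    method: str, params, pre: PreprocessConfig
) -> Callable[[np.ndarray], FeatureHistogram]:
    method = method.lower()

    def run(video: np.ndarray) -> FeatureHistogram:
        if pre.tim_target_length is not None:
            video = temporal_resample(video, pre.tim_target_length)
        if method == "mop":
            if pre.wiener_enabled and pre.wiener_apply_to == "mean_planes":
                return D.lbp_mop(
                    video, params, plane_filter=lambda im: wiener_filter(im, pre.wiener)
                )
            if pre.wiener_enabled:
                video = _filter_frames(video, pre.wiener)
            return D.lbp_mop(video, params)
        if pre.wiener_enabled:
            video = _filter_frames(video, pre.wiener)
        if method == "top":
            return D.lbp_top(video, params)
        if method == "sip":
            return D.lbp_sip(video, params)
        raise ValueError(f"unknown method {method!r}; expected top, sip or mop")

    return run


def _load_sample(row: pd.Series, corpus: Corpus | None) -> np.ndarray:
    if corpus is not None:
        for s in corpus.samples:
            if s.sample_id == row["sample_id"] and s.video is not None:
                return s.video
    return read_video(row["path"])


def extract_features(
    manifest: pd.DataFrame,
    method: str,
    params,
    pre: PreprocessConfig = PreprocessConfig(),
    *,
    corpus: Corpus | None = None,
    sidecar: str | Path | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """One feature row per manifest sample; per-sample failures collected.

    Returns ``(table, failures)``: the table is indexed by sample_id with
    columns named ``plane.block.bin``; failures is a list of
    ``{"sample_id", "error"}`` records (the run continues past them).
    ``sidecar`` optionally names a JSON file receiving the run metadata.
    """
    fn = _descriptor_fn(method, params, pre)
    rows: dict[str, np.ndarray] = {}
    columns: list[str] | None = None
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        try:
            hist = fn(_load_sample(row, corpus))
            if columns is None:
                columns = hist.column_names()
            elif len(columns) != len(hist):
                raise ValueError(
                    f"feature length {len(hist)} != {len(columns)} of earlier samples"
                )
            rows[sid] = hist.values
        except Exception as e:  # noqa: BLE001 - per-sample isolation is the contract
            failures.append({"sample_id": sid, "error": f"{type(e).__name__}: {e}"})
    if columns is None:
        raise ValueError("no sample could be processed")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "sample_id"
    if sidecar is not None:
        meta = {
            "method": method,
            "params": repr(params),
            "preprocess": repr(pre),
            "seed": seed,
            "n_samples": len(rows),
            "failures": failures,
            "numpy": np.__version__,
            "python": platform.python_version(),
        }
        Path(sidecar).write_text(json.dumps(meta, indent=2))
    return table, failures


def pyramid_extract_features(
    manifest: pd.DataFrame,
    method: str,
    params,
    pyramid: PyramidConfig,
    pre: PreprocessConfig = PreprocessConfig(),
    *,
    corpus: Corpus | None = None,
    level: int | str = "all",
) -> tuple[pd.DataFrame, list[dict]]:
    """Descriptor features on Gaussian-pyramid levels of each video.

    ``level`` selects a single level (int) or ``"all"`` for the
    concatenation of every level's feature histogram.
    """
    if pyramid.resize_to is None:
        raise ValueError("pyramid extraction requires a resize target")
    fn = _descriptor_fn(method, params, pre)
    rows: dict[str, np.ndarray] = {}
    columns: list[str] | None = None
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        try:
            video = _load_sample(row, corpus)
            vids = pyramid_video(video, pyramid)
            if level != "all":
                vids = [vids[int(level)]]
            hists = [fn(v) for v in vids]
            vec = np.concatenate([h.values for h in hists])
            if columns is None:
                level_ids = (
                    list(range(len(hists))) if level == "all" else [int(level)]
                )
                columns = [
                    f"L{k}.{name}"
                    for k, h in zip(level_ids, hists)
                    for name in h.column_names()
                ]
            rows[sid] = vec
        except Exception as e:  # noqa: BLE001
            failures.append({"sample_id": sid, "error": f"{type(e).__name__}: {e}"})
    if columns is None:
        raise ValueError("no sample could be processed")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "sample_id"
    return table, failures
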