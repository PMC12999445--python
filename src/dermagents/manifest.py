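"""Dataset round-tripping: PNG images plus a CSV manifest.

The manifest (columns: path, label, sequence_id, timestep, seed) is the
single exchange format between the simulate/train/evaluate commands and the
format a user would prepare for real dermoscopy data. Images are stored as
unnormalized 8-bit PNG; loading resizes to 224x224 and rescales to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .errors import DomainError
from .synthetic import IMAGE_SIZE, LesionImage, LesionSequence

MANIFEST_COLUMNS = ["path", "label", "sequence_id", "timestep", "seed"]


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)


def save_dataset(items, out_dir) -> Path:
    """Write lesion images/sequences as PNGs plus a manifest CSV.

    Returns the manifest path. Deterministic file naming, so a rerun with
    the same inputs is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seq_counter = 0
    img_counter = 0
    for item in items:
        if isinstance(item, LesionSequence):
            for t, frame in enumerate(item.frames):
                name = f"seq{seq_counter:05d}_t{t}.png"
                iio.imwrite(out_dir / name, _to_uint8(frame.pixels))
                rows.append(
                    {
                        "path": name,
                        "label": frame.label,
                        "sequence_id": seq_counter,
                        "timestep": t,
                        "seed": frame.seed,
                    }
                )
            seq_counter += 1
        else:
            name = f"img{img_counter:05d}.png"
            iio.imwrite(out_dir / name, _to_uint8(item.pixels))
            rows.append(
                {
                    "path": name,
                    "label": item.label,
                    "sequence_id": pd.NA,
                    "timestep": pd.NA,
                    "seed": item.seed,
                }
            )
            img_counter += 1
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DomainError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"manifest missing columns: {sorted(missing)}")
    return df


def _load_image(path: Path, label: int, seed: int) -> LesionImage:
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    raw = raw[..., :3]
    if raw.shape[:2] != (IMAGE_SIZE, IMAGE_SIZE):
        raw = np.asarray(
            Image.fromarray(raw).resize((IMAGE_SIZE, IMAGE_SIZE), Image.BILINEAR)
        )
    pixels = raw.astype(np.float64) / 255.0
    mask = estimate_lesion_mask(pixels)
    return LesionImage(pixels=pixels, label=int(label), lesion_mask=mask, seed=int(seed))


def estimate_lesion_mask(pixels: np.ndarray) -> np.ndarray:
    """Otsu threshold on the gray image; the lesion is the darker phase."""
    from skimage.filters import threshold_otsu

    gray = pixels.mean(axis=2)
    try:
        thr = threshold_otsu(gray)
    except ValueError:  # constant image
        return np.zeros(gray.shape, dtype=bool)
    mask = gray < thr
    if not mask.any():
        mask = gray <= gray.min()
    return mask


def load_dataset(manifest_path) -> list:
    """Read a manifest back into LesionImages / LesionSequences."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    items: list = []
    seq_rows = df[df["sequence_id"].notna()]
    for seq_id, group in seq_rows.groupby("sequence_id"):
        group = group.sort_values("timestep")
        frames = [
            _load_image(base / r["path"], r["label"], r["seed"])
            for _, r in group.iterrows()
        ]
        items.append(
            LesionSequence(frames=frames, area_growth_per_step=float("nan"),
                           darkening_per_step=float("nan"))
        )
    for _, r in df[df["sequence_id"].isna()].iterrows():
        items.append(_load_image(base / r["path"], r["label"], r["seed"]))
    return items
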