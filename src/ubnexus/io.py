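"""Readers/writers for the pipeline's on-disk formats.

Tables are tab-delimited with a header row and '.' decimals; gene sets
are GMT; images are multi-channel 16-bit TIFF with the channel order
recorded in the image description; ground truth and reports are JSON.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import CHANNELS


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(members)
             for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out[parts[0]] = [m for m in parts[2:] if m]
    return out


def write_image_stack(path: str | Path, stack: np.ndarray,
                      channels: Sequence[str] = CHANNELS) -> None:
    """Write a (C, H, W) stack as 16-bit TIFF with channel names in the
    description."""
    data = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack",
                     description=json.dumps({"axes": "CYX",
                                             "channels": list(channels)}))


def read_image_stack(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description
    channels = list(CHANNELS)
    try:
        meta = json.loads(desc)
        channels = list(meta.get("channels", channels))
    except (json.JSONDecodeError, TypeError):
        pass
    return data, channels


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
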