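"""Readers and writers for the pipeline's file dialects.

Conventions, stated once here and used everywhere:

* Localization tables: CSV with header
  ``frame,x_nm,y_nm,photons,background,crlb_nm,channel,n_merged``;
  coordinates are continuous nm with the center of camera pixel (0, 0) at
  (pixel_size/2, pixel_size/2).
* Image stacks: multi-page TIFF, written with the array's own dtype.
* Strand counts: a watson/crick bedGraph pair (0-based half-open 1 kb bins).
* Gene tables: TSV ``id, chrom, tss, tts, strand, length, fpkm`` declared
  1-based on disk and converted to 0-based in memory.
* Fiber tracts: TSV ``fiber_id, class, idu_um, cldu_um, origin_pair_id``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .locfit import LOC_COLUMNS

__all__ = [
    "write_localizations",
    "read_localizations",
    "write_stack",
    "read_stack",
    "write_bedgraph_pair",
    "read_bedgraph_pair",
    "write_gene_table",
    "read_gene_table",
    "write_fiber_table",
    "read_fiber_table",
]


def write_localizations(df: pd.DataFrame, path) -> None:
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    out = df.copy()
    for c in missing:  # allow bare x/y tables (e.g. bead fields)
        out[c] = {"frame": 0, "photons": 1.0, "background": 0.0,
                  "crlb_nm": np.nan, "channel": "ch0", "n_merged": 1}[c]
    out[LOC_COLUMNS].to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization file {path} lacks columns {missing}")
    return df


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_bedgraph_pair(bins: pd.DataFrame, watson_path, crick_path) -> None:
    from .okbias import BIN_BP

    for path, col in ((watson_path, "watson_count"), (crick_path, "crick_count")):
        out = pd.DataFrame(
            {
                "chrom": bins["chrom"],
                "start": bins["start"],
                "end": bins["start"] + BIN_BP,
                "value": bins[col],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_pair(watson_path, crick_path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "value"]
    w = pd.read_csv(watson_path, sep="\t", names=cols)
    c = pd.read_csv(crick_path, sep="\t", names=cols)
    if len(w) != len(c) or not (w["start"] == c["start"]).all():
        raise ValueError("watson/crick bedGraph files disagree on binning")
    return pd.DataFrame(
        {
            "chrom": w["chrom"],
            "start": w["start"].astype(int),
            "watson_count": w["value"].astype(int),
            "crick_count": c["value"].astype(int),
        }
    )


GENE_COLUMNS = ["id", "chrom", "tss", "tts", "strand", "length", "fpkm"]


def write_gene_table(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    out["tss"] = out["tss"] + 1  # 1-based on disk
    out["tts"] = out["tts"] + 1
    cols = GENE_COLUMNS + [c for c in out.columns if c not in GENE_COLUMNS]
    out[cols].to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} lacks columns {missing}")
    df["tss"] = df["tss"].astype(int) - 1
    df["tts"] = df["tts"].astype(int) - 1
    return df


FIBER_COLUMNS = ["fiber_id", "class", "idu_um", "cldu_um", "origin_pair_id"]


def write_fiber_table(tracts: pd.DataFrame, path) -> None:
    tracts[FIBER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fiber_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fiber table {path} lacks columns {missing}")
    return df
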