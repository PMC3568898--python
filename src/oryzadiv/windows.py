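"""Windowed substitution counts and transition/transversion ratios over the
three-way genome comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
VALID = set("ACGT")


class UndefinedRatioError(ValueError):
    """No transversions in scope: the ts/tv ratio is undefined."""


@dataclass(frozen=True)
class WindowConfig:
    window_bp: int = 10_000
    step_bp: int = 10_000
    annotation_filter: str | None = "non-exonic"

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window_bp and step_bp must be positive")


def classify_substitution(base_x: str | None, base_y: str | None) -> str | None:
    """'transition' | 'transversion' | 'identical'; None when not comparable."""
    if base_x is None or base_y is None:
        return None
    bx, by = base_x.upper(), base_y.upper()
    if bx not in VALID or by not in VALID:
        return None
    if bx == by:
        return "identical"
    return "transition" if (bx, by) in TRANSITIONS else "transversion"


def _annotation_mask(df: pd.DataFrame, annotation_filter: str | None) -> pd.Series:
    if annotation_filter is None or "annotation_class" not in df:
        return pd.Series(True, index=df.index)
    if annotation_filter == "non-exonic":
        # complement of all annotated exons: intronic plus non-transcribed
        return df["annotation_class"].isin(["non-exonic", "non-transcribed"])
    return df["annotation_class"] == annotation_filter


def _comparable(df: pd.DataFrame, pair: tuple[str, str]) -> pd.DataFrame:
    bx, by = df[f"base_{pair[0]}"], df[f"base_{pair[1]}"]
    ok = bx.isin(list(VALID)) & by.isin(list(VALID))
    return df[ok]


def window_counts(
    columns: pd.DataFrame,
    cfg: WindowConfig = WindowConfig(),
    pair: tuple[str, str] = ("osj", "og"),
) -> pd.DataFrame:
    """Substitution counts in sliding windows along each chromosome.

    Window w covers [w*step, w*step + window_bp); counts are differing
    comparable sites passing the annotation filter.  Windows without any
    comparable site carry no_data=True (distinct from zero substitutions).
    Output columns: chrom, start, end, count, comparable_sites, no_data.
    """
    rows = []
    for chrom, sub in columns.groupby("chrom"):
        sub = sub[_annotation_mask(sub, cfg.annotation_filter)]
        comp = _comparable(sub, pair)
        diffs = comp[comp[f"base_{pair[0]}"] != comp[f"base_{pair[1]}"]]
        last_pos = int(sub["pos"].max()) if len(sub) else 0
        n_windows = last_pos // cfg.step_bp + 1
        for w in range(n_windows):
            start = w * cfg.step_bp
            end = start + cfg.window_bp
            in_w = (comp["pos"] >= start) & (comp["pos"] < end)
            in_w_d = (diffs["pos"] >= start) & (diffs["pos"] < end)
            n_comp = int(in_w.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "count": int(in_w_d.sum()),
                    "comparable_sites": n_comp,
                    "no_data": n_comp == 0,
                }
            )
    return pd.DataFrame(rows)


def tstv_ratio(
    columns: pd.DataFrame,
    pair: tuple[str, str] = ("osj", "og"),
    annotation_filter: str | None = None,
    chrom: str | None = None,
) -> float:
    """Transitions / transversions over comparable differing sites."""
    df = columns
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    df = df[_annotation_mask(df, annotation_filter)]
    comp = _comparable(df, pair)
    bx = comp[f"base_{pair[0]}"].str.upper()
    by = comp[f"base_{pair[1]}"].str.upper()
    differing = bx != by
    is_ts = (
        ((bx == "A") & (by == "G")) | ((bx == "G") & (by == "A"))
        | ((bx == "C") & (by == "T")) | ((bx == "T") & (by == "C"))
    )
    n_ts = int((differing & is_ts).sum())
    n_tv = int((differing & ~is_ts).sum())
    if n_tv == 0:
        raise UndefinedRatioError("no transversions in scope")
    return n_ts / n_tv


def write_window_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)
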