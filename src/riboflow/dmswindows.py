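"""DMS structure-probing normalization and sliding-window TE analyses.

DMS modifies unpaired A and C bases; raw per-nucleotide stop/mutation counts
are turned into reactivities in [0, 1] by a windowed 2-8% style rule: within
each 150-nt window, the divisor is the smallest count among the top 5% of
A/C nucleotides, everything is divided by it, and the top 5% saturate at 1.
Windows with too few A/C positions in the top 5% (fewer than 10) or a zero
divisor are masked entirely.

The window analyses average an arbitrary per-nucleotide "energy" track (DMS
reactivity or computational folding energy) in sliding windows aligned to
the start codon, normalize per gene by the gene's mean window value,
correlate each window position with TE across genes under a Bonferroni
correction over the window count, and locate the first downstream dip
(a global minimum within a centred 90-nt span).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ReactivityProfile", "WindowProfile",
    "normalize_dms", "window_profile", "te_window_correlation",
    "find_energy_dip",
]


@dataclasses.dataclass
class ReactivityProfile:
    """Per-nucleotide reactivities in [0, 1] with a missing-data mask and a
    log of windows that were skipped (fully masked) and why."""

    values: np.ndarray
    mask: np.ndarray          # True = missing
    skipped_windows: list[tuple[int, int, str]]


@dataclasses.dataclass
class WindowProfile:
    """Cross-gene window statistics aligned to the start codon.

    ``positions`` are window start offsets in nt (negative = upstream);
    ``mean`` the across-gene average of per-gene-normalized window means;
    ``n_genes`` how many genes informed each position.  Correlation columns
    are filled by :func:`te_window_correlation`.
    """

    positions: np.ndarray
    mean: np.ndarray
    n_genes: np.ndarray
    r: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_corr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.positions, "mean": self.mean,
                "n": self.n_genes}
        if self.r is not None:
            data.update({"r": self.r, "p_raw": self.p_raw,
                         "p_corr": self.p_corr})
        return pd.DataFrame(data)


def normalize_dms(
    raw_counts: np.ndarray,
    sequence: str,
    window: int = 150,
    top_fraction: float = 0.05,
    min_top_ac: int = 10,
) -> ReactivityProfile:
    """Window-normalize raw DMS counts into [0, 1] reactivities.

    Per ``window``-nt tile (a gene shorter than one window is a single
    whole-gene window): the divisor is the minimum count among the top 5%
    (rounded up, ties by count order) of A/C nucleotides; all values are
    divided by it and capped at 1, so the top 5% sit exactly at 1.  Windows
    with fewer than ``min_top_ac`` A/C positions in the top 5% or with a
    zero divisor are masked entirely.  G/T positions are always masked (DMS
    does not report them).
    """
    raw = np.asarray(raw_counts, dtype=float)
    seq = sequence.upper().replace("U", "T")
    if raw.ndim != 1 or len(seq) != raw.size:
        raise ValueError("counts and sequence must be 1-D and equal length")
    if np.any(raw < 0):
        raise ValueError("raw DMS counts must be non-negative")
    n = raw.size
    values = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    skipped: list[tuple[int, int, str]] = []
    is_ac = np.array([b in "AC" for b in seq])

    starts = range(0, n, window) if n > window else [0]
    for s in starts:
        e = min(s + window, n)
        ac_idx = np.nonzero(is_ac[s:e])[0] + s
        if ac_idx.size == 0:
            skipped.append((s, e, "no_ac_positions"))
            continue
        # top 5% of A/C positions by count, ties at the boundary kept: with
        # discrete counts the boundary value is often shared, and without
        # ties a 150-nt window can hold at most 8 top positions, which could
        # never satisfy the >= 10 rule
        n_top = math.ceil(top_fraction * ac_idx.size)
        order = np.sort(raw[ac_idx])[::-1]
        boundary = order[min(n_top, ac_idx.size) - 1]
        top = ac_idx[raw[ac_idx] >= boundary]
        if top.size < min_top_ac:
            skipped.append((s, e, "too_few_top_ac"))
            continue
        divisor = float(raw[top].min())
        if divisor <= 0:
            skipped.append((s, e, "zero_divisor"))
            continue
        vals = np.minimum(raw[s:e] / divisor, 1.0)
        sel = is_ac[s:e]
        values[s:e][sel] = vals[sel]
        mask[s:e][sel] = False
    return ReactivityProfile(values, mask, skipped)


def _gene_window_means(
    track: np.ndarray,
    start_offset: int,
    width: int,
    upstream: int,
    downstream: int,
) -> dict[int, float]:
    """Window means for one gene at every start position -upstream..+downstream.

    ``track`` is the per-nt signal with NaN for missing; ``start_offset`` is
    the index of the first CDS nucleotide within the track.  Window means
    are taken over non-missing positions (a DMS-derived track never reports
    G/T bases); windows that run off the track or are entirely missing are
    omitted.
    """
    out: dict[int, float] = {}
    n = track.size
    for pos in range(-upstream, downstream + 1):
        a = start_offset + pos
        b = a + width
        if a < 0 or b > n:
            continue
        seg = track[a:b]
        valid = ~np.isnan(seg)
        if not valid.any():
            continue
        out[pos] = float(seg[valid].mean())
    return out


def window_profile(
    tracks: Mapping[str, np.ndarray],
    start_offsets: Mapping[str, int],
    width: int = 40,
    upstream: int = 30,
    downstream: int = 250,
) -> tuple[WindowProfile, dict[str, dict[int, float]]]:
    """Sliding-window means across genes, aligned by start codon.

    Per gene, window means are normalized by the gene's mean over its own
    windows; the profile averages these across genes per position.  Genes
    with no valid window are excluded.  Also returns the per-gene normalized
    window tables (used by :func:`te_window_correlation`).
    """
    per_gene: dict[str, dict[int, float]] = {}
    for g, track in tracks.items():
        wm = _gene_window_means(
            np.asarray(track, dtype=float), start_offsets[g],
            width, upstream, downstream,
        )
        if not wm:
            continue
        norm = float(np.mean(list(wm.values())))
        if norm == 0:
            continue
        per_gene[g] = {p: v / norm for p, v in wm.items()}
    positions = np.arange(-upstream, downstream + 1)
    mean = np.full(positions.size, np.nan)
    n_genes = np.zeros(positions.size, dtype=int)
    for i, pos in enumerate(positions):
        vals = [wm[pos] for wm in per_gene.values() if pos in wm]
        n_genes[i] = len(vals)
        if vals:
            mean[i] = float(np.mean(vals))
    return WindowProfile(positions, mean, n_genes), per_gene


def te_window_correlation(
    per_gene_windows: Mapping[str, Mapping[int, float]],
    te: Mapping[str, float],
    profile: WindowProfile,
    min_genes: int = 10,
    n_windows: int | None = None,
) -> WindowProfile:
    """Spearman correlation between window signal and TE at each position.

    Bonferroni correction multiplies raw p-values by the number of windows
    (by default the profile's own position count, 281 for the standard
    30-upstream/250-downstream span; pass ``n_windows=280`` to reproduce the
    published correction exactly).  Positions with fewer than ``min_genes``
    genes are NA.
    """
    if n_windows is None:
        n_windows = profile.positions.size
    r = np.full(profile.positions.size, np.nan)
    p_raw = np.full(profile.positions.size, np.nan)
    for i, pos in enumerate(profile.positions):
        pairs = [
            (wm[pos], te[g])
            for g, wm in per_gene_windows.items()
            if pos in wm and g in te
        ]
        if len(pairs) < min_genes:
            continue
        xv, yv = zip(*pairs)
        rho, p = sps.spearmanr(xv, yv)
        r[i], p_raw[i] = float(rho), float(p)
    p_corr = np.minimum(1.0, p_raw * n_windows)
    return WindowProfile(profile.positions, profile.mean, profile.n_genes,
                         r=r, p_raw=p_raw, p_corr=p_corr)


def find_energy_dip(
    profile: WindowProfile | np.ndarray,
    span: int = 90,
    positions: np.ndarray | None = None,
) -> int:
    """First downstream position that is a global minimum within a centred
    ``span``-nt window of the profile.

    The span is half-open [p - span//2, p + span//2), clipped at the profile
    edges; ties break toward the smallest coordinate, so a flat profile
    returns the first scanned position.  Only positions at or downstream of
    the start codon are scanned.
    """
    if isinstance(profile, WindowProfile):
        vals = profile.mean
        pos = profile.positions
    else:
        vals = np.asarray(profile, dtype=float)
        pos = np.asarray(positions) if positions is not None else np.arange(vals.size)
    if vals.size < 1:
        raise ValueError("empty profile")
    half = span // 2
    for i in range(vals.size):
        if pos[i] < 0 or np.isnan(vals[i]):
            continue
        lo = max(0, i - half)
        hi = min(vals.size, i + half)
        seg = vals[lo:hi]
        if np.nanmin(seg) == vals[i] and np.nanargmin(seg) + lo == i:
            return int(pos[i])
    raise ValueError("no downstream minimum found")
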