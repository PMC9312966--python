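"""The 1080-column window feature engine.

Every window instant is described by 22 descriptor families computed on each
of the 36 (electrode, band) segments: 14 univariate codes and 8 bivariate
ones, the latter evaluated twice -- method A (MA) against the segment
shifted back by one window step, and method B (MB) against the null vector.
14*36 + 8*72 = 1080 feature columns, plus the binary target "Actual YN".

Degenerate inputs (constant segments, zero-variance pairs) map to 0 for
ratio-type descriptors so the table is always finite.  Method-B distances
against the null vector have closed forms (DTW reduces to the L1 norm, the
common-subsequence length to the zero-symbol count) which are used as exact
fast paths; unit tests pin them to the generic dynamic programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._kernels import dtw_cost, lcs_length, lz76_phrase_count, nakamura_periods
from .preprocess import WindowedBank

TARGET_COLUMN = "Actual YN"

UNIVARIATE_CODES = ("KC", "LE", "LL", "LU", "SH", "AP", "IP", "PD", "PP", "SG", "SP", "HM", "KU", "SD")
BIVARIATE_CODES = ("CC", "CE", "DT", "ED", "JE", "LC", "LD", "MI")
METHODS = ("MA", "MB")
BAND_NAMES = ("B8", "B13", "B21", "B30", "B40", "B70")

_ENTROPY_UNI = frozenset({"SH", "LE"})
_COMPLEXITY = frozenset({"KC", "LL", "LU"})
_SEISMIC = frozenset({"AP", "IP", "PD", "PP", "SG", "SP"})
_STATISTICAL = frozenset({"HM", "KU", "SD"})
_ENTROPY_BIV = frozenset({"CE", "JE", "MI"})
_DISTANCE = frozenset({"CC", "ED", "DT"})
_SYMBOLIC = frozenset({"LC", "LD"})


@dataclass(frozen=True)
class FeatureConfig:
    """Estimator knobs shared by the histogram and symbolic descriptors.

    ``n_bins`` amplitude bins feed the Shannon/joint/conditional entropies
    and mutual information; ``n_symbols`` equal-width levels feed the
    common-subsequence and edit distances; ``pp_alpha`` is the forgetting
    factor of the recursive predominant-period estimator; ``le_eps`` guards
    the log-energy entropy against log(0).
    """

    n_bins: int = 16
    n_symbols: int = 8
    pp_alpha: float = 0.99
    le_eps: float = 1e-12


def feature_columns(
    n_channels: int = 6, bands: Sequence[str] = BAND_NAMES
) -> list[str]:
    """Canonical column order: (code, method, electrode, band)."""
    cols = []
    for code in UNIVARIATE_CODES + BIVARIATE_CODES:
        methods = METHODS if code in BIVARIATE_CODES else (None,)
        for method in methods:
            for e in range(1, n_channels + 1):
                for band in bands:
                    tag = f"{code}-{method}" if method else code
                    cols.append(f"{tag}-E{e}-{band}")
    return cols


def parse_column(name: str) -> tuple[str, str | None, int, str]:
    """Split ``CODE[-METHOD]-Ei-Bj`` into (code, method, electrode, band)."""
    parts = name.split("-")
    if len(parts) == 3:
        code, e, band = parts
        method = None
    elif len(parts) == 4:
        code, method, e, band = parts
        if method not in METHODS:
            raise ValueError(f"unknown method in feature name {name!r}")
    else:
        raise ValueError(f"malformed feature name {name!r}")
    if not (e.startswith("E") and e[1:].isdigit()):
        raise ValueError(f"malformed electrode in feature name {name!r}")
    if (method is None) != (code in UNIVARIATE_CODES):
        raise ValueError(f"feature name {name!r} has wrong arity")
    return code, method, int(e[1:]), band


# ---------------------------------------------------------------------------
# histogram entropies


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _hist_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts / x.size


def _range(v: np.ndarray) -> tuple[float, float]:
    lo, hi = float(v.min()), float(v.max())
    return (lo, hi) if hi > lo else (lo, lo + 1.0)


def entropy_features(
    x: np.ndarray, y: np.ndarray | None = None, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Shannon / log-energy entropy of ``x``; joint quantities if ``y`` given.

    SH uses a ``n_bins`` equal-width amplitude histogram over the segment's
    own range, in natural-log units.  With a second segment: JE is the
    entropy of the ``n_bins`` x ``n_bins`` joint histogram, CE = JE - SH(y),
    MI = SH(x) + SH(y) - JE.  Against a constant ``y`` (method B's null
    vector) JE and CE collapse exactly to SH(x).
    """
    x = np.asarray(x, dtype=float)
    out = {
        "SH": _entropy(_hist_probs(x, config.n_bins)),
        "LE": float(np.log(x * x + config.le_eps).sum()),
    }
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.size != x.size:
            raise ValueError(f"segment lengths differ: {x.size} vs {y.size}")
        counts, _, _ = np.histogram2d(
            x, y, bins=config.n_bins, range=[_range(x), _range(y)]
        )
        je = _entropy(counts.ravel() / x.size)
        sh_y = _entropy(_hist_probs(y, config.n_bins))
        out["JE"] = je
        out["CE"] = je - sh_y
        out["MI"] = out["SH"] + sh_y - je
    return out


# ---------------------------------------------------------------------------
# complexity


def complexity_features(x: np.ndarray) -> dict[str, float]:
    """Median-binarized LZ76 complexity and its two normalizations.

    ``c`` is the LZ76 phrase count of the bit string ``x > median(x)``;
    KC = c*log2(n)/n, and LL/LU divide ``c`` by the asymptotic phrase bound
    n/log2(n) rounded up respectively down, so LL <= LU always.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("complexity features need at least 2 samples")
    bits = (x > np.median(x)).astype(np.uint8)
    c = lz76_phrase_count(bits)
    log2n = np.log2(n)
    bound = n / log2n
    return {
        "KC": c * log2n / n,
        "LL": c / float(np.ceil(bound)),
        "LU": c / float(np.floor(bound)),
    }


# ---------------------------------------------------------------------------
# seismic-analogy descriptors


def seismic_features(
    x: np.ndarray, fs: float, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Earthquake-early-warning descriptors applied to an EEG segment.

    With ``i* = argmax |x|`` and time-to-peak ``t* = i*/fs`` from the window
    start: PD is the peak displacement |x[i*]|, IP = 1/t*, SP = t*^2 and
    SG = (PD/t*)^2 (all three 0 when the peak is the first sample); PP is
    the recursive predominant period 2*pi*sqrt(X/D) at the window end and AP
    its mean over the window, X and D being exponentially smoothed squared
    displacement and velocity.
    """
    x = np.asarray(x, dtype=float)
    i_star = int(np.argmax(np.abs(x)))
    t_star = i_star / fs
    pd_ = float(np.abs(x[i_star]))
    pp, ap = nakamura_periods(x, fs, config.pp_alpha)
    return {
        "AP": ap,
        "IP": 1.0 / t_star if t_star > 0 else 0.0,
        "PD": pd_,
        "PP": pp,
        "SG": (pd_ / t_star) ** 2 if t_star > 0 else 0.0,
        "SP": t_star**2,
    }


# ---------------------------------------------------------------------------
# statistical descriptors


def statistical_features(x: np.ndarray) -> dict[str, float]:
    """Population SD, Hjorth mobility and Pearson kurtosis (m4/m2^2).

    Zero-variance segments map to 0 for the two ratio descriptors.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("statistical features need at least 3 samples")
    var = float(np.var(x))
    if var == 0.0:
        return {"HM": 0.0, "KU": 0.0, "SD": 0.0}
    centered = x - x.mean()
    m2 = var
    m4 = float(np.mean(centered**4))
    dvar = float(np.var(np.diff(x)))
    return {"HM": float(np.sqrt(dvar / var)), "KU": m4 / (m2 * m2), "SD": float(np.sqrt(var))}


# ---------------------------------------------------------------------------
# distance descriptors


def distance_features(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Euclidean distance, max-lag cross-correlation index, and DTW cost.

    CC is the maximum over all lags of the biased normalized
    cross-correlation (0 if either input has zero variance).  DTW uses the
    absolute-difference local cost with no window or slope constraint;
    against the null vector it equals the L1 norm exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"segment lengths differ: {x.size} vs {y.size}")
    n = x.size
    out = {"ED": float(np.linalg.norm(x - y))}

    sx, sy = float(x.std()), float(y.std())
    if sx == 0.0 or sy == 0.0:
        out["CC"] = 0.0
    else:
        r = np.correlate(x - x.mean(), y - y.mean(), mode="full") / (n * sx * sy)
        out["CC"] = float(r.max())

    if not y.any():
        out["DT"] = float(np.abs(x).sum())
    elif not x.any():
        out["DT"] = float(np.abs(y).sum())
    else:
        out["DT"] = float(dtw_cost(x, y))
    return out


# ---------------------------------------------------------------------------
# symbolic descriptors


def _symbolize(v: np.ndarray, lo: float, hi: float, n_symbols: int) -> np.ndarray:
    sym = ((v - lo) / (hi - lo) * n_symbols).astype(np.int64)
    return np.clip(sym, 0, n_symbols - 1)


def symbolic_features(
    x: np.ndarray, y: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Longest-common-subsequence ratio and Levenshtein distance.

    Both signals are quantized to ``n_symbols`` equal-width levels over the
    union of their ranges; LC is the LCS length divided by n, LD the
    unit-cost edit distance (a count).  Against a constant symbol string the
    closed forms LC = count/n and LD = n - count are exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"segment lengths differ: {x.size} vs {y.size}")
    n = x.size
    lo = min(float(x.min()), float(y.min()))
    hi = max(float(x.max()), float(y.max()))
    if hi == lo:  # both segments constant and equal
        return {"LC": 1.0, "LD": 0.0}
    sx = _symbolize(x, lo, hi, config.n_symbols)
    sy = _symbolize(y, lo, hi, config.n_symbols)
    if (sy == sy[0]).all():
        count = int((sx == sy[0]).sum())
        return {"LC": count / n, "LD": float(n - count)}
    if (sx == sx[0]).all():
        count = int((sy == sx[0]).sum())
        return {"LC": count / n, "LD": float(n - count)}
    lcs = int(lcs_length(sx, sy))
    qa = (sx + 48).astype(np.uint8).tobytes()
    qb = (sy + 48).astype(np.uint8).tobytes()
    ld = edlib.align(qa, qb, task="distance")["editDistance"]
    return {"LC": lcs / n, "LD": float(ld)}


# ---------------------------------------------------------------------------
# table assembly


def _segment_values(
    cur: np.ndarray,
    prev: np.ndarray,
    zeros: np.ndarray,
    need_uni: frozenset[str],
    need_ma: frozenset[str],
    need_mb: frozenset[str],
    fs: float,
    config: FeatureConfig,
) -> dict[str, float]:
    out: dict[str, float] = {}
    if need_uni & _ENTROPY_UNI:
        out.update({k: v for k, v in entropy_features(cur, config=config).items()})
    if need_uni & _COMPLEXITY:
        out.update(complexity_features(cur))
    if need_uni & _SEISMIC:
        out.update(seismic_features(cur, fs, config))
    if need_uni & _STATISTICAL:
        out.update(statistical_features(cur))
    for method, other, needed in (("MA", prev, need_ma), ("MB", zeros, need_mb)):
        if needed & _ENTROPY_BIV:
            ent = entropy_features(cur, other, config=config)
            for code in ("CE", "JE", "MI"):
                out[f"{code}-{method}"] = ent[code]
        if needed & _DISTANCE:
            for code, v in distance_features(cur, other).items():
                out[f"{code}-{method}"] = v
        if needed & _SYMBOLIC:
            for code, v in symbolic_features(cur, other, config).items():
                out[f"{code}-{method}"] = v
    return out


def build_feature_table(
    bank: WindowedBank,
    columns: Iterable[str] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Compute the feature table for a window stream.

    Rows are window instants (index = terminal time in seconds); columns are
    the 1080 canonical features plus the target column, or the requested
    subset of feature ``columns`` (canonical order is preserved).  Output is
    deterministic given the bank.
    """
    if len(bank) == 0:
        raise ValueError("cannot build a feature table from an empty window stream")
    all_cols = feature_columns(bank.n_channels, bank.band_names)
    if columns is None:
        cols = all_cols
    else:
        requested = set(columns)
        unknown = requested - set(all_cols)
        if unknown:
            raise KeyError(f"unknown feature columns: {sorted(unknown)[:5]}")
        cols = [c for c in all_cols if c in requested]

    # group requested work by (electrode, band) segment
    per_segment: dict[tuple[int, str], dict[str, set[str]]] = {}
    placements: list[tuple[int, tuple[int, str], str]] = []  # col idx, segment, out key
    for idx, name in enumerate(cols):
        code, method, e, band = parse_column(name)
        seg = (e, band)
        groups = per_segment.setdefault(seg, {"uni": set(), "MA": set(), "MB": set()})
        if method is None:
            groups["uni"].add(code)
            placements.append((idx, seg, code))
        else:
            groups[method].add(code)
            placements.append((idx, seg, f"{code}-{method}"))
    frozen = {
        seg: tuple(frozenset(g[k]) for k in ("uni", "MA", "MB")) for seg, g in per_segment.items()
    }

    L_smp, _ = bank.window.samples(bank.fs)
    zeros = np.zeros(L_smp)
    values = np.empty((len(bank), len(cols)))
    for i in range(len(bank)):
        seg_out: dict[tuple[int, str], dict[str, float]] = {}
        for seg, (need_uni, need_ma, need_mb) in frozen.items():
            e, band = seg
            cur, prev = bank.segment(i, e - 1, band)
            try:
                seg_out[seg] = _segment_values(
                    cur, prev, zeros, need_uni, need_ma, need_mb, bank.fs, config
                )
            except Exception as exc:
                raise RuntimeError(f"feature computation failed for E{e}-{band}: {exc}") from exc
        for idx, seg, key in placements:
            values[i, idx] = seg_out[seg][key]

    if not np.isfinite(values).all():
        bad = [cols[j] for j in np.unique(np.argwhere(~np.isfinite(values))[:, 1])]
        raise RuntimeError(f"non-finite feature values in columns: {bad[:5]}")

    table = pd.DataFrame(values, columns=cols, index=pd.Index(bank.instants, name="t_s"))
    table[TARGET_COLUMN] = bank.labels
    return table


def write_feature_table(table: pd.DataFrame, path, chunksize: int = 512) -> None:
    """Stream a feature table to CSV (bounded memory for long recordings)."""
    table.to_csv(path, index_label="t_s", chunksize=chunksize)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="t_s")
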