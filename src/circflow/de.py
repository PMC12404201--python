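"""Differential circRNA expression from BSJ counts.

Replicates are pooled within group and the two groups compared with a
conditional binomial exact test: given the total count n = countA + countB,
countA is Binomial(n, libA/(libA+libB)) under the null of equal rates.  The
two-sided p-value sums the probabilities of outcomes no more likely than the
observed one; the fold change uses 0.5 prior counts,
log2FC = log2(((countA+0.5)/libA) / ((countB+0.5)/libB)).

Classification presets mirror the thresholds used for circRNA classes:

- ``population``: logCPM > -5, P < 0.1, log2FC > 0 (neuronal) or < 0
  (nonneuronal), everything else "other".
- ``population_display``: the stricter display cutoffs
  (P < 0.05, logCPM > -5.4, |log2FC| >= 1).
- ``mutant_elav`` / ``mutant_elav_fne``: |log2FC| >= 0.5 / 0.3 and
  logCPM > -5.4, signed into elav_down / elav_up; else "unchanged".

No multiple-testing correction is applied, mirroring the raw-P criteria.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

PRESETS = {
    "population": dict(kind="population", min_logcpm=-5.0, max_p=0.1, min_abs_fc=0.0),
    "population_display": dict(kind="population", min_logcpm=-5.4, max_p=0.05, min_abs_fc=1.0),
    "mutant_elav": dict(kind="mutant", min_logcpm=-5.4, min_abs_fc=0.5),
    "mutant_elav_fne": dict(kind="mutant", min_logcpm=-5.4, min_abs_fc=0.3),
}


def log_cpm(count, lib_size):
    """log2 counts-per-million with a 0.5 prior count:
    log2((count + 0.5) / (lib_size + 1) * 1e6)."""
    count = np.asarray(count, dtype=float)
    lib = np.asarray(lib_size, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library size must be positive")
    out = np.log2((count + 0.5) / (lib + 1.0) * 1e6)
    return float(out) if out.ndim == 0 else out


def exact_rate_test(count_a: int, lib_a: float, count_b: int, lib_b: float):
    """Conditional binomial exact test; returns (log2FC, p)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    fc = math.log2(((count_a + 0.5) / lib_a) / ((count_b + 0.5) / lib_b))
    n = count_a + count_b
    if n == 0:
        return 0.0, 1.0
    p0 = lib_a / (lib_a + lib_b)
    p = stats.binomtest(count_a, n, p0).pvalue
    return fc, float(p)


def run_de(
    counts: pd.DataFrame,
    group_a: str,
    group_b: str,
    lib_sizes: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Group contrast over a long counts table (circ_id, group, bsj).

    Replicate rows are summed within group.  Library sizes default to the
    per-group total BSJ counts.  logCPM is the average of the two group
    logCPMs; log2FC is group_a over group_b.
    """
    pooled = counts.groupby(["circ_id", "group"], as_index=False)["bsj"].sum()
    wide = pooled.pivot(index="circ_id", columns="group", values="bsj").fillna(0)
    for g in (group_a, group_b):
        if g not in wide.columns:
            wide[g] = 0
    ca = wide[group_a].astype(int)
    cb = wide[group_b].astype(int)
    if lib_sizes is None:
        lib_sizes = {group_a: float(ca.sum()), group_b: float(cb.sum())}
    la, lb = lib_sizes[group_a], lib_sizes[group_b]
    rows = []
    for circ_id, a, b in zip(wide.index, ca, cb):
        fc, p = exact_rate_test(int(a), la, int(b), lb)
        lcpm = 0.5 * (log_cpm(int(a), la) + log_cpm(int(b), lb))
        rows.append({"circ_id": circ_id, "logCPM": lcpm, "log2FC": fc, "p": p})
    return pd.DataFrame(rows)


def classify(results: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Attach a class label per circRNA under a named threshold preset."""
    if contrast not in PRESETS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[contrast]
    out = results.copy()
    labels = []
    for r in out.itertuples(index=False):
        if cfg["kind"] == "population":
            floor_ok = r.logCPM > cfg["min_logcpm"]
            p_ok = r.p < cfg["max_p"]
            thr = cfg["min_abs_fc"]
            up = r.log2FC >= thr if thr > 0 else r.log2FC > 0
            down = r.log2FC <= -thr if thr > 0 else r.log2FC < 0
            if floor_ok and p_ok and up:
                labels.append("neuronal")
            elif floor_ok and p_ok and down:
                labels.append("nonneuronal")
            else:
                labels.append("other")
        else:
            affected = r.logCPM > cfg["min_logcpm"] and abs(r.log2FC) >= cfg["min_abs_fc"]
            if affected and r.log2FC < 0:
                labels.append("elav_down")
            elif affected:
                labels.append("elav_up")
            else:
                labels.append("unchanged")
    out["label"] = labels
    return out
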