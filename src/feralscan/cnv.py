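"""Copy-number variation: call filtering, CNVR consolidation by
reciprocal overlap, per-sample copy-number matrices, and the VST scan
between phenotype groups.

Quality filtering keeps calls with length strictly over 1 kb, a
t-test p-value strictly under 0.001 and a zero-mapping-quality read
fraction (q0) strictly under 0.5.  Calls of the same type whose
pairwise overlap is at least 50% of *both* call lengths are linked, and
single-linkage clusters become CNV regions (CNVRs) spanning the union
of their members.  VST, the copy-number analog of FST, is

    VST = (VT - VS) / VT,   VS = (VA nA + VB nB) / (nA + nB)

with population (ddof = 0) variances, so 0 <= VST <= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DIPLOID_CN = 2.0  # copy number assigned to samples with no call in a CNVR


def filter_calls(
    calls: pd.DataFrame,
    min_len: int = 1000,
    max_p: float = 0.001,
    max_q0: float = 0.5,
) -> pd.DataFrame:
    """Quality filter; all three predicates are strict inequalities."""
    length = calls["end"] - calls["start"]
    keep = (length > min_len) & (calls["p_value"] < max_p) & (calls["q0"] < max_q0)
    return calls[keep].reset_index(drop=True)


@dataclass
class CNVR:
    contig: str
    start: int
    end: int
    cnv_type: str
    member_index: list[int] = field(default_factory=list)  # rows of the call table
    copy_numbers: dict[str, float] = field(default_factory=dict)  # carriers only
    v_st: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def sample_vector(self, samples: list[str]) -> np.ndarray:
        return np.array(
            [self.copy_numbers.get(s, DIPLOID_CN) for s in samples], dtype=float
        )


def _reciprocal_link(s1: int, e1: int, s2: int, e2: int, frac: float) -> bool:
    ov = min(e1, e2) - max(s1, s2)
    return ov >= frac * (e1 - s1) and ov >= frac * (e2 - s2)


def merge_cnvrs(calls: pd.DataFrame, reciprocal: float = 0.5) -> list[CNVR]:
    """Single-linkage clustering of same-type calls under the reciprocal-
    overlap criterion.  Order-independent and idempotent: re-merging the
    resulting CNVRs (as calls) reproduces them.
    """
    if not 0 < reciprocal <= 1:
        raise ValueError(f"reciprocal fraction must be in (0, 1], got {reciprocal}")
    out: list[CNVR] = []
    for (contig, cnv_type), sub in calls.groupby(["contig", "type"], sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy(dtype=int)
        ends = sub["end"].to_numpy(dtype=int)
        n = len(idx)
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        max_end = 0
        for i in range(n):
            for j in range(i + 1, n):
                if starts[j] >= ends[i]:
                    break
                if _reciprocal_link(
                    starts[i], ends[i], starts[j], ends[j], reciprocal
                ):
                    union(i, j)
            max_end = max(max_end, ends[i])
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            rows = sub.iloc[members]
            cn: dict[str, list[float]] = {}
            if "sample" in rows.columns and "copy_number" in rows.columns:
                for r in rows.itertuples():
                    cn.setdefault(r.sample, []).append(float(r.copy_number))
            out.append(
                CNVR(
                    contig=contig,
                    start=int(rows["start"].min()),
                    end=int(rows["end"].max()),
                    cnv_type=cnv_type,
                    member_index=[int(idx[m]) for m in members],
                    copy_numbers={s: float(np.mean(v)) for s, v in cn.items()},
                )
            )
    out.sort(key=lambda r: (r.contig, r.start, r.end, r.cnv_type))
    return out


def copy_number_matrix(cnvrs: list[CNVR], samples: list[str]) -> pd.DataFrame:
    """CNVR x sample matrix; non-carriers get the diploid reference CN."""
    mat = pd.DataFrame(
        [r.sample_vector(samples) for r in cnvrs],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "contig": [r.contig for r in cnvrs],
            "start": [r.start for r in cnvrs],
            "end": [r.end for r in cnvrs],
            "type": [r.cnv_type for r in cnvrs],
        }
    )
    return pd.concat([meta, mat], axis=1)


def vst_scan(
    cnvrs: list[CNVR],
    phenotype_map: dict[str, str],
    group_a: str,
    group_b: str,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-CNVR VST between two phenotype groups plus top-tail flags.

    CNVRs with zero total variance are flagged uninformative and are
    excluded from the empirical quantile; the remaining CNVRs with VST
    at or above the ``1 - top_fraction`` quantile are candidates.
    """
    sa = [s for s, g in phenotype_map.items() if g == group_a]
    sb = [s for s, g in phenotype_map.items() if g == group_b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both phenotype groups need at least 2 samples")
    rows = []
    for r in cnvrs:
        xa = r.sample_vector(sa)
        xb = r.sample_vector(sb)
        both = np.concatenate([xa, xb])
        v_t = float(both.var())  # population variance, ddof=0
        if v_t == 0.0:
            vst = float("nan")
        else:
            v_s = (xa.var() * len(xa) + xb.var() * len(xb)) / (len(xa) + len(xb))
            vst = (v_t - v_s) / v_t
        r.v_st = vst
        rows.append(
            {
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "type": r.cnv_type,
                "v_st": vst,
                "uninformative": v_t == 0.0,
            }
        )
    df = pd.DataFrame(rows)
    informative = df[~df["uninformative"]]
    if len(informative):
        thr = float(np.quantile(informative["v_st"], 1.0 - top_fraction))
        df["candidate"] = ~df["uninformative"] & (df["v_st"] >= thr)
    else:
        df["candidate"] = False
    return df
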