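"""Bias removal and free-energy statistics of dangling intermediates.

A constant-force simulation samples configurations with an extra
-f_C * x term in the Hamiltonian.  The unbiased (zero-force) ensemble is
recovered by giving every frame the weight w_i ~ exp(-beta f_C x_i).
With those weights, the free-energy difference between the 3'-dangling
(FLIP5) and 5'-dangling (FLIP3) intermediates of a junction pair in NN
context c is

    g(c) = k_B T ln [ W_FLIP5(c) / W_FLIP3(c) ],

positive when the 3'-dangling intermediate is the more populated one.
Uncertainties come from a moving-block bootstrap over time blocks,
which preserves the autocorrelation of the state series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .junction_states import FLIP3, FLIP5, JunctionStateSeries, OpeningEvent
from .sbm_forcefield import KBT_PN_NM_296K

__all__ = [
    "FrameWeights",
    "NNFreeEnergyTable",
    "all_contexts",
    "reweight",
    "dangling_dg",
    "bootstrap_se",
    "autocorr_time",
    "detailed_balance_report",
]


def all_contexts(nucleic_type: str) -> List[str]:
    """The 16 nearest-neighbor context labels of a nucleic acid type."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"} if nucleic_type.upper() == "DNA" else {
        "A": "U", "U": "A", "C": "G", "G": "C"}
    bases = sorted(comp)
    return [f"{b}{c}/{comp[b]}{comp[c]}" for b in bases for c in bases]


@dataclass
class FrameWeights:
    """Normalized statistical weights removing the pulling bias."""

    weights: np.ndarray
    beta_f_per_nm: float
    log_norm: float  # log of the unnormalized weight sum

    @property
    def ess(self) -> float:
        """Kish effective sample size 1 / sum(w^2)."""
        return float(1.0 / np.sum(self.weights**2))


def reweight(x_nm: np.ndarray, f_pn: float, temperature: float | None = None) -> FrameWeights:
    """Frame weights w_i ~ exp(-beta f_C x_i) removing the -f_C x bias.

    x is the end-to-end distance in nm and f_pn the applied force in pN;
    beta f_C = f_pn / 4.09 per nm at the 296 K calibration, independent
    of the reduced simulation temperature (which only rescales the
    energy unit; `temperature` is accepted for interface symmetry).
    """
    x = np.asarray(x_nm, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite end-to-end distances")
    beta_f = f_pn / KBT_PN_NM_296K
    logw = -beta_f * x
    m = logw.max() if len(logw) else 0.0
    w = np.exp(logw - m)
    s = w.sum()
    return FrameWeights(weights=w / s, beta_f_per_nm=beta_f, log_norm=float(m + np.log(s)))


@dataclass
class NNFreeEnergyTable:
    """Per-context free-energy differences g (k_B T) with bootstrap SE."""

    data: pd.DataFrame  # columns: context, g, se, n5, n3
    nucleic_type: str = "RNA"
    f_pn: float = 0.0
    metadata: Dict = field(default_factory=dict)

    def g(self, context: str) -> float:
        row = self.data.loc[self.data.context == context]
        if row.empty:
            raise KeyError(f"context {context!r} not in table")
        return float(row.g.iloc[0])

    def observed(self, context: str) -> bool:
        row = self.data.loc[self.data.context == context]
        return (not row.empty) and bool(np.isfinite(row.g.iloc[0]))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, nucleic_type: str = "RNA", f_pn: float = 0.0) -> "NNFreeEnergyTable":
        return cls(data=pd.read_csv(path), nucleic_type=nucleic_type, f_pn=f_pn)

    @classmethod
    def uniform(cls, nucleic_type: str, g: float = 0.0) -> "NNFreeEnergyTable":
        """Constant-g table over all 16 contexts (toy input for scoring)."""
        ctx = all_contexts(nucleic_type)
        return cls(
            data=pd.DataFrame({"context": ctx, "g": g, "se": 0.0, "n5": np.nan, "n3": np.nan}),
            nucleic_type=nucleic_type,
        )


def _flip_weight_sums(
    series_list: Sequence[JunctionStateSeries],
    weight_list: Sequence[FrameWeights],
    idx_list: Optional[Sequence[np.ndarray]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Summed normalized weight of FLIP5/FLIP3 junction frames per context."""
    sums: Dict[str, List[float]] = {}
    for run, (series, fw) in enumerate(zip(series_list, weight_list)):
        w = fw.weights
        sel = np.arange(series.n_frames) if idx_list is None else idx_list[run]
        st = series.states[sel]
        ju = series.junction[sel]
        ws = w[sel]
        for k in range(1, series.n_pairs):  # the last pair has no context
            ctx = series.contexts[k - 1]
            at_k = ju == k
            m5 = at_k & (st == FLIP5)
            m3 = at_k & (st == FLIP3)
            if ctx not in sums:
                sums[ctx] = [0.0, 0.0, 0.0, 0.0]
            sums[ctx][0] += ws[m5].sum()
            sums[ctx][1] += ws[m3].sum()
            sums[ctx][2] += int(m5.sum())
            sums[ctx][3] += int(m3.sum())
    return {c: tuple(v) for c, v in sums.items()}


def dangling_dg(
    series: JunctionStateSeries | Sequence[JunctionStateSeries],
    weights: FrameWeights | Sequence[FrameWeights],
    nucleic_type: str = "RNA",
    temperature_kbt: float = 1.0,
) -> NNFreeEnergyTable:
    """Free-energy difference between dangling intermediates per context.

    g = k_B T ln(W_FLIP5 / W_FLIP3) with W the summed unbiased frame
    weight; contexts where either intermediate was never observed get
    g = NaN (flagged, not zeroed).  Multiple runs are pooled.
    """
    series_list = [series] if isinstance(series, JunctionStateSeries) else list(series)
    weight_list = [weights] if isinstance(weights, FrameWeights) else list(weights)
    if len(series_list) != len(weight_list):
        raise ValueError("need one FrameWeights per state series")
    for s, fw in zip(series_list, weight_list):
        if s.n_frames != len(fw.weights):
            raise ValueError("series and weights are not aligned")
    sums = _flip_weight_sums(series_list, weight_list)
    rows = []
    for ctx, (w5, w3, n5, n3) in sorted(sums.items()):
        g = temperature_kbt * math.log(w5 / w3) if (w5 > 0 and w3 > 0) else float("nan")
        rows.append({"context": ctx, "g": g, "se": np.nan, "n5": int(n5), "n3": int(n3)})
    return NNFreeEnergyTable(data=pd.DataFrame(rows), nucleic_type=nucleic_type)


def autocorr_time(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time of a series (frames, >= 0.5)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return 0.5
    if max_lag is None:
        max_lag = min(n // 4, 2000)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 : n - 1 + max_lag + 1]
    acf /= acf[0]
    tau = 0.5
    for lag in range(1, max_lag + 1):
        if acf[lag] <= 0.05:
            break
        tau += acf[lag]
    return float(tau)


def bootstrap_se(
    series: JunctionStateSeries | Sequence[JunctionStateSeries],
    weights: FrameWeights | Sequence[FrameWeights],
    n_boot: int = 1000,
    block_len: int | None = None,
    seed: int = 0,
    nucleic_type: str = "RNA",
    temperature_kbt: float = 1.0,
) -> NNFreeEnergyTable:
    """Moving-block bootstrap SE of the per-context g estimates.

    Time blocks of `block_len` frames (default: 5x the junction-state
    autocorrelation time) are resampled with replacement within each
    run; SE is the standard deviation of g across resamples.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    series_list = [series] if isinstance(series, JunctionStateSeries) else list(series)
    weight_list = [weights] if isinstance(weights, FrameWeights) else list(weights)
    rng = np.random.default_rng(seed)
    table = dangling_dg(series_list, weight_list, nucleic_type, temperature_kbt)
    if block_len is None:
        taus = [autocorr_time((s.states == FLIP5).astype(float)) for s in series_list]
        block_len = max(1, int(round(5 * max(taus))))
    for s in series_list:
        if s.n_frames < block_len:
            raise ValueError(f"series of {s.n_frames} frames shorter than block {block_len}")

    contexts = list(table.data.context)
    gs = np.full((n_boot, len(contexts)), np.nan)
    for b in range(n_boot):
        idx_list = []
        for s in series_list:
            n = s.n_frames
            n_blocks = int(math.ceil(n / block_len))
            starts = rng.integers(0, max(n - block_len, 0) + 1, size=n_blocks)
            idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:n]
            idx_list.append(idx)
        sums = _flip_weight_sums(series_list, weight_list, idx_list)
        for c, ctx in enumerate(contexts):
            w5, w3 = sums.get(ctx, (0.0, 0.0, 0, 0))[:2]
            if w5 > 0 and w3 > 0:
                gs[b, c] = temperature_kbt * math.log(w5 / w3)
    se = np.nanstd(gs, axis=0, ddof=1)
    out = table.data.copy()
    out["se"] = se
    out["block_len"] = block_len
    return NNFreeEnergyTable(data=out, nucleic_type=nucleic_type, metadata={"n_boot": n_boot, "seed": seed})


def detailed_balance_report(events: Iterable[OpeningEvent], alpha: float = 0.01) -> pd.DataFrame:
    """Two-proportion z-test of opening vs closing pathway fractions.

    In equilibrium, opening and closing events traverse each pathway
    with statistically identical probabilities; a small p-value flags a
    violation.  Contexts with fewer than 2 events in either direction
    are skipped (flagged in the 'skipped' column).
    """
    counts: Dict[Optional[str], np.ndarray] = {}
    for ev in events:
        if ev.pathway == "direct":
            continue
        c = counts.setdefault(ev.context, np.zeros(4, dtype=int))
        i = (0 if ev.direction == "opening" else 2) + (0 if ev.pathway == "via_FLIP5" else 1)
        c[i] += 1
    rows = []
    for ctx, (o5, o3, c5, c3) in sorted(counts.items(), key=lambda t: str(t[0])):
        n_open, n_close = o5 + o3, c5 + c3
        row = {"context": ctx, "open_via5": o5, "open_via3": o3,
               "close_via5": c5, "close_via3": c3, "skipped": False,
               "z": np.nan, "p": np.nan, "reject": False}
        if n_open < 2 or n_close < 2:
            row["skipped"] = True
        else:
            p1, p2 = o5 / n_open, c5 / n_close
            pool = (o5 + c5) / (n_open + n_close)
            denom = math.sqrt(pool * (1 - pool) * (1 / n_open + 1 / n_close))
            if denom == 0:
                z, p = 0.0, 1.0
            else:
                z = (p1 - p2) / denom
                p = 2 * stats.norm.sf(abs(z))
            row.update(z=z, p=p, reject=bool(p < alpha))
        rows.append(row)
    return pd.DataFrame(rows)
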