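"""The helix-unwindability (h-unwind) index.

SF1/SF2 helicases load on an overhang of one strand (the tracking
strand), translocate into the duplex and peel off the complementary
(displaced) strand.  The unwinding bottleneck is the population of
still-stacked nucleobases on the displaced strand at the ss/ds
junction: unwinding is easy when the displaced base is the one that
flips out readily.

At every junction the free-energy difference g between the two dangling
intermediates (from the nearest-neighbor table) sets the probability
that the displaced strand's base is the flipped one,

    p = 1 / (1 + exp(-s g / k_B T)),

with s = +1 when the displaced base's flip is the FLIP5 (3'-dangling)
intermediate of that context - i.e. the displaced strand presents its
5' terminus at the junction, as it does for a 3'->5' helicase - and
s = -1 otherwise.  The h-unwind index is the mean of p over the
duplex's N-1 junction steps in the helicase's travel direction: higher
values predict more efficient unwinding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .helix_builder import reverse_complement
from .thermo_stats import NNFreeEnergyTable

__all__ = [
    "UnwindingTask",
    "UnwindScore",
    "hunwind",
    "design_constructs",
    "rank_predictions",
]


@dataclass(frozen=True)
class UnwindingTask:
    """A duplex plus helicase geometry (tracking strand and polarity)."""

    strand1: str  # 5'->3'
    strand2: str  # 5'->3', reverse complement of strand1
    tracking: int  # 1 or 2
    directionality: str  # '5to3' or '3to5'
    nucleic_type: str = "DNA"
    name: str = ""

    def __post_init__(self) -> None:
        if self.tracking not in (1, 2):
            raise ValueError("tracking must be 1 or 2")
        if self.directionality not in ("5to3", "3to5"):
            raise ValueError("directionality must be '5to3' or '3to5'")
        if self.strand2.upper() != reverse_complement(self.strand1, self.nucleic_type):
            raise ValueError("strands are not reverse complements")

    @property
    def tracking_strand(self) -> str:
        return self.strand1 if self.tracking == 1 else self.strand2

    @property
    def displaced_strand(self) -> str:
        return self.strand2 if self.tracking == 1 else self.strand1


@dataclass
class UnwindScore:
    """h-unwind value and its per-step decomposition."""

    h_unwind: float
    step_probabilities: np.ndarray  # displaced-base flip probability per junction
    contexts: List[str]
    aggregate: str = "mean"
    table_meta: Dict = field(default_factory=dict)


def _step_contexts(task: UnwindingTask) -> List[Tuple[str, int]]:
    """(context label, sign) for each junction step in travel order.

    The context is written with the strand presenting its 5' terminus
    at the junction on top (junction base first, inward neighbor
    second), matching the simulation's labeling; sign = +1 when the
    displaced base's flip is the FLIP5 intermediate of that context.
    """
    t = task.tracking_strand.upper()
    d = reverse_complement(t, task.nucleic_type)  # d[j] pairs t[N+1-j], both 1-based
    n = len(t)
    steps: List[Tuple[str, int]] = []
    if task.directionality == "5to3":
        # helicase enters at the tracking strand's 5' end; the tracking
        # strand presents the junction 5' terminus, the displaced base
        # flip is FLIP3
        for i in range(1, n):
            b1, c1 = t[i - 1], t[i]
            b2, c2 = d[n - i], d[n - i - 1]
            steps.append((f"{b1}{c1}/{b2}{c2}", -1))
    else:
        # entry at the tracking strand's 3' end; the displaced strand
        # presents the junction 5' terminus, its flip is FLIP5
        for i in range(n, 1, -1):
            j = n + 1 - i
            b1, c1 = d[j - 1], d[j]
            b2, c2 = t[i - 1], t[i - 2]
            steps.append((f"{b1}{c1}/{b2}{c2}", +1))
    return steps


def hunwind(
    task: UnwindingTask,
    table: NNFreeEnergyTable,
    temperature_kbt: float = 1.0,
    aggregate: str = "mean",
) -> UnwindScore:
    """h-unwind index of a duplex for a given helicase geometry.

    aggregate 'mean' (default) averages the per-step displaced-base
    flip probabilities; 'geometric' exponentiates the mean
    log-probability (a sensitivity-analysis alternative that penalizes
    single hard steps more strongly).
    """
    if aggregate not in ("mean", "geometric"):
        raise ValueError("aggregate must be 'mean' or 'geometric'")
    steps = _step_contexts(task)
    probs = []
    contexts = []
    for ctx, sign in steps:
        if not table.observed(ctx):
            raise KeyError(f"context {ctx!r} missing from the free-energy table")
        g = table.g(ctx)
        p = 1.0 / (1.0 + math.exp(-sign * g / temperature_kbt))
        probs.append(p)
        contexts.append(ctx)
    probs_arr = np.array(probs)
    if aggregate == "mean":
        h = float(probs_arr.mean())
    else:
        h = float(np.exp(np.mean(np.log(probs_arr))))
    return UnwindScore(
        h_unwind=h,
        step_probabilities=probs_arr,
        contexts=contexts,
        aggregate=aggregate,
        table_meta={"nucleic_type": table.nucleic_type, "f_pn": table.f_pn},
    )


#: default 21-nt homopurine strand of the designed constructs (an
#: (AG)-repeat homopurine class sequence; the complementary strand is
#: the homopyrimidine (TC)-repeat)
PU_STRAND_21 = "AG" * 10 + "A"


def design_constructs(pu_strand: str = PU_STRAND_21) -> Dict[str, UnwindingTask]:
    """The four designed unwinding tasks: Pu/Py displaced strand for
    5'->3' and 3'->5' helicases.

    Each Pu/Py pair shares the same 21-bp double helix; only the
    tracking/displaced roles (and hence the helicase entry end) are
    swapped.
    """
    pu = pu_strand.upper()
    py = reverse_complement(pu, "DNA")
    tasks = {
        "Pu_5-3": UnwindingTask(pu, py, tracking=2, directionality="5to3", name="Pu_5-3"),
        "Py_5-3": UnwindingTask(pu, py, tracking=1, directionality="5to3", name="Py_5-3"),
        "Pu_3-5": UnwindingTask(pu, py, tracking=2, directionality="3to5", name="Pu_3-5"),
        "Py_3-5": UnwindingTask(pu, py, tracking=1, directionality="3to5", name="Py_3-5"),
    }
    for name, task in tasks.items():
        displaced = task.displaced_strand
        expected = set("AG") if name.startswith("Pu") else set("TC")
        assert set(displaced) <= expected, f"{name}: displaced strand {displaced}"
    return tasks


def rank_predictions(scores: Dict[str, UnwindScore], tie_tol: float = 1e-12) -> pd.DataFrame:
    """Descending h-unwind ranking with tie flags."""
    if len(scores) < 2:
        raise ValueError("need at least two scores to rank")
    df = pd.DataFrame(
        [{"name": k, "h_unwind": v.h_unwind, "aggregate": v.aggregate} for k, v in scores.items()]
    ).sort_values("h_unwind", ascending=False, kind="mergesort").reset_index(drop=True)
    h = df.h_unwind.to_numpy()
    tied = np.zeros(len(h), dtype=bool)
    for i in range(len(h) - 1):
        if abs(h[i] - h[i + 1]) <= tie_tol:
            tied[i] = tied[i + 1] = True
    df["tied"] = tied
    df["rank"] = np.arange(1, len(h) + 1)
    return df
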