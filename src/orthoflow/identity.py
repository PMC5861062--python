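"""Per-ortholog percent identity, distribution summaries, closest-relative
classification, and locally weighted regression.

Identity between two species in one ortholog group is computed over the
group's retained conserved-block columns; the denominator counts only
columns where both rows are non-gap.  The three-way comparison labels each
ortholog by which of two comparator species it is more similar to from a
focal species — the per-gene signal behind closest-relative arguments in
comparative genomics — and a lowess smoother summarises the joint
distribution of the two identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import BlockedAlignment
from .seqio import GAP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentityRecord:
    """Block-restricted percent identity for one group and species pair."""

    group_id: str
    species_a: str
    species_b: str
    percent: float
    n_columns: int

    def __post_init__(self) -> None:
        if self.species_a > self.species_b:
            a, b = self.species_a, self.species_b
            object.__setattr__(self, "species_a", b)
            object.__setattr__(self, "species_b", a)
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percent identity {self.percent} outside [0, 100]")
        if self.n_columns < 1:
            raise ValueError("a record needs >= 1 comparable column")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.species_a, self.species_b)))


@dataclass
class DistributionSummary:
    pair: tuple[str, str]
    n: int
    q1: float
    median: float
    q3: float
    notch: float  # half-width of the median notch


@dataclass
class LowessFit:
    x: np.ndarray       # sorted x
    fitted: np.ndarray  # fitted values at sorted x
    r_squared: float


@dataclass
class ComparisonTable:
    """Closest-relative classification of each ortholog."""

    focal: str
    comp_a: str
    comp_b: str
    table: pd.DataFrame  # columns: group, id_a, id_b, label
    counts: dict[str, int]
    fractions: dict[str, float]
    smoother: LowessFit | None = None


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------


def pairwise_identity(
    rows: Sequence[str], retained: Sequence[int], i: int, j: int
) -> tuple[float, int] | None:
    """Percent identity between rows i and j over the retained columns.

    The denominator counts retained columns where both rows are non-gap.
    Returns ``(percent, n_comparable)``, or None when no column is
    comparable.
    """
    if i == j:
        raise ValueError("need two distinct rows")
    if not retained:
        raise ValueError("retained column set is empty")
    a, b = rows[i], rows[j]
    comparable = 0
    matches = 0
    for c in retained:
        ca, cb = a[c], b[c]
        if ca == GAP or cb == GAP:
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    if comparable == 0:
        return None
    return 100.0 * matches / comparable, comparable


def compute_identities(
    blocked: Mapping[str, BlockedAlignment], species: Sequence[str]
) -> list[IdentityRecord]:
    """Identity records for every species pair of every blocked group."""
    out: list[IdentityRecord] = []
    species = list(species)
    for gid in sorted(blocked):
        ba = blocked[gid]
        if not ba.retained:
            logger.info("group %s skipped: no retained columns", gid)
            continue
        rows = {sp: ba.msa.row_by_species(sp) for sp in species}
        for i, sa in enumerate(species):
            for sb in species[i + 1:]:
                res = pairwise_identity([rows[sa], rows[sb]], ba.retained, 0, 1)
                if res is None:
                    logger.info("group %s pair (%s, %s): no comparable columns", gid, sa, sb)
                    continue
                pct, ncol = res
                out.append(IdentityRecord(gid, sa, sb, pct, ncol))
    return out


def summarize_distribution(
    records: Iterable[IdentityRecord] | Sequence[float],
    pair: tuple[str, str],
) -> DistributionSummary:
    """Boxplot-style summary: linear-interpolation quartiles and the
    standard notch half-width ``1.58 * IQR / sqrt(n)``."""
    vals = [
        (r.percent if isinstance(r, IdentityRecord) else float(r))
        for r in records
        if not isinstance(r, IdentityRecord) or r.pair == tuple(sorted(pair))
    ]
    if not vals:
        raise ValueError(f"no identity records for pair {pair}")
    arr = np.asarray(vals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # type-7 interpolation
    notch = 1.58 * (q3 - q1) / np.sqrt(arr.size)
    return DistributionSummary(tuple(sorted(pair)), arr.size, float(q1), float(med), float(q3), float(notch))


# ---------------------------------------------------------------------------
# three-way comparison
# ---------------------------------------------------------------------------


def three_way(
    records: Iterable[IdentityRecord],
    focal: str,
    comp_a: str,
    comp_b: str,
    tie_eps: float = 0.0,
) -> ComparisonTable:
    """Classify each ortholog by its closer comparator.

    A group is ``closer-a`` when identity(focal, a) exceeds
    identity(focal, b) by more than ``tie_eps``; symmetric for
    ``closer-b``; otherwise ``tie``.  Groups lacking either pair record
    are excluded (logged).  Fractions are over all classified groups with
    ties reported separately.
    """
    if tie_eps < 0:
        raise ValueError("tie_eps must be >= 0")
    pa = tuple(sorted((focal, comp_a)))
    pb = tuple(sorted((focal, comp_b)))
    id_a: dict[str, float] = {}
    id_b: dict[str, float] = {}
    for r in records:
        if r.pair == pa:
            id_a[r.group_id] = r.percent
        elif r.pair == pb:
            id_b[r.group_id] = r.percent
    common = sorted(set(id_a) & set(id_b))
    dropped = (set(id_a) | set(id_b)) - set(common)
    if dropped:
        logger.info("three_way: %d group(s) lacking a pair record excluded", len(dropped))
    rows = []
    for gid in common:
        diff = id_a[gid] - id_b[gid]
        if diff > tie_eps:
            label = "closer-a"
        elif -diff > tie_eps:
            label = "closer-b"
        else:
            label = "tie"
        rows.append((gid, id_a[gid], id_b[gid], label))
    df = pd.DataFrame(rows, columns=["group", "id_a", "id_b", "label"])
    counts = {
        lab: int((df["label"] == lab).sum()) for lab in ("closer-a", "closer-b", "tie")
    }
    total = len(df)
    fractions = {lab: (c / total if total else 0.0) for lab, c in counts.items()}
    return ComparisonTable(focal, comp_a, comp_b, df, counts, fractions)


# ---------------------------------------------------------------------------
# lowess
# ---------------------------------------------------------------------------


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    out[np.abs(u) >= 1.0] = 0.0
    return out


def lowess_fit(
    x: Sequence[float],
    y: Sequence[float],
    frac: float = 2.0 / 3.0,
    robust_iters: int = 3,
) -> LowessFit:
    """Locally weighted linear regression (classic lowess).

    At each observed x the nearest ``k = int(frac * n)`` neighbours are
    weighted by the tricube kernel of scaled distance and a weighted
    straight line is evaluated at that x; ``robust_iters`` bisquare
    re-weighting passes down-weight outlying residuals.  The coefficient
    of determination is ``1 - SS_res / SS_tot`` over fitted values at the
    observed x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("lowess needs >= 3 points")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    if np.all(xs == xs[0]):  # degenerate: vertical data
        fitted = np.full(n, ys.mean())
    else:
        k = max(2, min(n, int(frac * n)))
        delta = np.ones(n)  # robustness weights
        fitted = np.empty(n)
        for _ in range(robust_iters + 1):
            left = 0
            for i in range(n):
                # slide the k-neighbour window along sorted x
                right = left + k - 1
                while right < n - 1 and xs[right + 1] - xs[i] < xs[i] - xs[left]:
                    left += 1
                    right += 1
                d = max(xs[i] - xs[left], xs[right] - xs[i])
                xi = xs[left : right + 1]
                yi = ys[left : right + 1]
                if d <= 0:
                    w = np.ones_like(xi)
                else:
                    w = _tricube((xi - xs[i]) / d)
                w = w * delta[left : right + 1]
                sw = w.sum()
                if sw <= 0:
                    fitted[i] = yi.mean()
                    continue
                xbar = np.dot(w, xi) / sw
                var = np.dot(w, (xi - xbar) ** 2)
                if var <= 1e-12 * max(1.0, xbar * xbar):
                    fitted[i] = np.dot(w, yi) / sw
                else:
                    b = np.dot(w, (xi - xbar) * yi) / var
                    a = np.dot(w, yi) / sw
                    fitted[i] = a + b * (xs[i] - xbar)
            resid = ys - fitted
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            u = resid / (6.0 * s)
            delta = np.clip(1.0 - u**2, 0.0, None) ** 2

    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LowessFit(xs, fitted, r2)


def attach_smoother(
    cmp_table: ComparisonTable, frac: float = 2.0 / 3.0, robust_iters: int = 3
) -> ComparisonTable:
    """Fit the lowess smoother of id_b against id_a and attach it."""
    df = cmp_table.table
    cmp_table.smoother = lowess_fit(
        df["id_a"].to_numpy(), df["id_b"].to_numpy(), frac, robust_iters
    )
    return cmp_table


def write_identities(records: Sequence[IdentityRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#group\tspecies_a\tspecies_b\tidentity\tn_columns\n")
        for r in sorted(records, key=lambda r: (r.group_id, r.species_a, r.species_b)):
            fh.write(f"{r.group_id}\t{r.species_a}\t{r.species_b}\t{r.percent:.4f}\t{r.n_columns}\n")
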