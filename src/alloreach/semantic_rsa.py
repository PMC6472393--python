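"""Dissimilarity estimation from multi-arrangement data, pooling, MDS, triads.

In the multi-arrangement task participants drag item icons in a 2-D arena so
that on-screen distance encodes dissimilarity; later trials present adaptive
subsets, so each trial yields a partial, arbitrarily scaled distance table.
The estimator combines trials iteratively: starting from the full first
trial, it alternates (a) a per-trial least-squares scale factor aligning
each trial's distances to the current estimate over the shared pairs with
(b) an evidence-weighted per-pair average of the scaled distances, where a
pair's evidence is its squared scaled on-screen distance (pairs dragged
close together carry little metric evidence). The final matrix is normalized
to unit maximum so pooled dissimilarities live in [0, 1].

The subset selector is a simplified lift-the-weakest heuristic: it grows a
subset from the pair with the least accumulated evidence, adding items while
the gained evidence per unit trial cost keeps up with the best ratio seen.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


@dataclass(frozen=True)
class ArrangementTrial:
    """Items and 2-D screen positions of one arrangement trial."""

    items: tuple[str, ...]
    positions: np.ndarray  # (n_items, 2)

    def __post_init__(self) -> None:
        if len(self.items) < 3:
            raise ValueError("arrangement trials need at least 3 items")
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item in one trial")
        if np.asarray(self.positions).shape != (len(self.items), 2):
            raise ValueError("positions must be (n_items, 2)")


@dataclass
class RDM:
    """Symmetric item-pairwise dissimilarity matrix."""

    items: tuple[str, ...]
    matrix: np.ndarray
    normalization: str = "unit-max"  # "unit-max" | "unit-rms" | "raw"
    evidence: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.shape != (len(self.items), len(self.items)):
            raise ValueError("matrix shape must match the item list")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("RDM diagonal must be zero")
        if np.nanmin(m) < 0:
            raise ValueError("dissimilarities must be >= 0")
        self.matrix = m

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def pair_mean(self, subset) -> float:
        idx = [self.items.index(s) for s in subset]
        return float(np.mean([self.matrix[i, j]
                              for i, j in itertools.combinations(idx, 2)]))


@dataclass(frozen=True)
class TriadStats:
    """Candidate-triad distance statistics against random triads."""

    triad: tuple[str, str, str]
    triad_mean: float
    random_mean: float
    m_diff: float
    t: float
    p: float
    n_random: int


def trial_distances(trial: ArrangementTrial) -> pd.DataFrame:
    """Euclidean screen distances for all item pairs present in the trial."""
    d = pdist(np.asarray(trial.positions, float))
    pairs = list(itertools.combinations(trial.items, 2))
    return pd.DataFrame({"item_a": [a for a, _ in pairs],
                         "item_b": [b for _, b in pairs],
                         "distance": d})


def _pair_indices(items_all: tuple[str, ...], trial: ArrangementTrial) -> np.ndarray:
    """Condensed-form indices of the trial's pairs within the full item set."""
    n = len(items_all)
    pos = {it: i for i, it in enumerate(items_all)}

    def cidx(i, j):
        i, j = (i, j) if i < j else (j, i)
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    idx = [pos[a] for a in trial.items]
    return np.array([cidx(idx[a], idx[b])
                     for a, b in itertools.combinations(range(len(idx)), 2)])


def estimate_rdm(
    trials: list[ArrangementTrial],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RDM:
    """Iterative evidence-weighted RDM estimation from partial arrangements.

    The first trial must contain every item. Pairs never observed across
    trials remain NaN (flagged with a warning); non-convergence after
    ``max_iter`` sweeps returns the best estimate with a warning.
    """
    if not trials:
        raise ValueError("no trials")
    items = tuple(trials[0].items)
    npair = len(items) * (len(items) - 1) // 2

    dists = [pdist(np.asarray(t.positions, float)) for t in trials]
    pair_idx = [_pair_indices(items, t) for t in trials]

    est = np.full(npair, np.nan)
    est[pair_idx[0]] = dists[0]
    rms = np.sqrt(np.mean(dists[0] ** 2))
    if rms == 0:
        raise ValueError("first trial is degenerate (all items co-located)")
    est /= rms

    evidence = np.zeros(npair)
    for _ in range(max_iter):
        num = np.zeros(npair)
        den = np.zeros(npair)
        for d, idx in zip(dists, pair_idx):
            e = est[idx]
            ss = np.nansum(d * d)
            scale = np.nansum(d * e) / ss if ss > 0 else 1.0
            scaled = scale * d
            w = scaled ** 2
            num[idx] += w * scaled
            den[idx] += w
        with np.errstate(invalid="ignore", divide="ignore"):
            new = num / den
        new_rms = np.sqrt(np.nanmean(new ** 2))
        if new_rms > 0:
            new = new / new_rms
        delta = np.nanmax(np.abs(new - est)) if np.any(np.isfinite(new)) else 0.0
        est, evidence = new, den
        if delta < tol:
            break
    else:
        warnings.warn("RDM estimation did not converge; returning the best estimate")

    if np.any(~np.isfinite(est)):
        warnings.warn("some item pairs were never observed; entries left missing")
    peak = np.nanmax(est)
    if peak > 0:
        est = est / peak
    return RDM(items, squareform(est, checks=False),
               normalization="unit-max", evidence=evidence)


def select_next_subset(
    rdm: RDM,
    evidence: np.ndarray,
    size_bounds: tuple[int, int] = (3, 12),
    cost_exponent: float = 1.5,
    evidence_ceiling: float | None = None,
    seed=0,
) -> tuple[str, ...]:
    """Greedy lift-the-weakest subset for the next arrangement trial.

    Starts from the pair with the least accumulated evidence, then adds the
    item that gains the most still-needed evidence per unit of added trial
    cost (cost grows as subset size to ``cost_exponent``), stopping once the
    marginal gain-per-cost falls below the best running ratio or the upper
    size bound is reached. Signals completion (returns an empty tuple) when
    every pair has reached the evidence ceiling.
    """
    items = rdm.items
    n = len(items)
    ev = squareform(np.asarray(evidence, float), checks=False) if np.ndim(evidence) == 1 \
        else np.asarray(evidence, float)
    offdiag = ~np.eye(n, dtype=bool)
    if evidence_ceiling is not None and ev[offdiag].min() >= evidence_ceiling:
        return ()  # every pair saturated: selection complete
    ceiling = float(np.max(ev)) if evidence_ceiling is None else float(evidence_ceiling)
    need = np.maximum(ceiling - ev, 0.0)
    if need[offdiag].max() <= 0:
        need = offdiag.astype(float)  # uniform evidence: every pair equally needy
    np.fill_diagonal(need, 0.0)

    rng = np.random.default_rng(seed)
    jitter = rng.random((n, n)) * 1e-12
    jitter = (jitter + jitter.T) / 2
    i, j = np.unravel_index(np.argmax(need + jitter), need.shape)
    chosen = [i, j]
    lo, hi = size_bounds

    def cost(size):
        return size ** cost_exponent

    gained = need[i, j]
    best_ratio = gained / cost(2)
    while len(chosen) < hi:
        mask = np.ones(n, bool)
        mask[chosen] = False
        cand = np.flatnonzero(mask)
        util = need[np.ix_(cand, chosen)].sum(axis=1) + jitter[cand, chosen[0]]
        k = cand[np.argmax(util)]
        marginal_cost = cost(len(chosen) + 1) - cost(len(chosen))
        ratio = util.max() / marginal_cost
        if len(chosen) >= lo and ratio < best_ratio:
            break
        gained += util.max()
        best_ratio = max(best_ratio, gained / cost(len(chosen) + 1))
        chosen.append(int(k))
    while len(chosen) < lo:
        mask = np.ones(n, bool)
        mask[chosen] = False
        chosen.append(int(np.flatnonzero(mask)[0]))
    return tuple(items[c] for c in sorted(chosen))


def pool_rdms(rdms: list[RDM]) -> RDM:
    """Entrywise mean of unit-max-normalized RDMs across participants."""
    if not rdms:
        raise ValueError("no RDMs to pool")
    items = rdms[0].items
    mats = []
    for r in rdms:
        if r.items != items:
            raise ValueError("item label mismatch across RDMs")
        m = r.matrix
        peak = np.nanmax(m)
        mats.append(m / peak if peak > 0 else m)
    return RDM(items, np.nanmean(mats, axis=0), normalization="unit-max")


def mds_embed(rdm: RDM, dims: int = 2, n_init: int = 4, seed=0,
              init: str = "classical_mds") -> tuple[np.ndarray, float]:
    """Metric MDS embedding (SMACOF stress majorization, seeded restarts).

    The default classical-scaling initialisation lands exactly on
    Euclidean-embeddable inputs; ``init="random"`` gives independent seeded
    restarts instead. Returns (coordinates, normalized stress-1 =
    sqrt(sum (d_hat - d)^2 / sum d^2)).
    """
    from sklearn.manifold import MDS

    if dims < 1:
        raise ValueError("dims must be >= 1")
    m = rdm.matrix
    if np.any(~np.isfinite(m)):
        raise ValueError("RDM contains missing entries; cannot embed")
    if init == "classical_mds":
        n_init = 1  # deterministic start: restarts would be identical
    mds = MDS(n_components=dims, metric="precomputed", metric_mds=True,
              n_init=n_init, init=init,
              random_state=int(np.random.default_rng(seed).integers(2**31)),
              normalized_stress=False)
    coords = mds.fit_transform(m)
    fitted = pdist(coords)
    target = squareform(m, checks=False)
    denom = float((target ** 2).sum())
    stress1 = float(np.sqrt(((fitted - target) ** 2).sum() / denom)) if denom > 0 else 0.0
    return coords, stress1


def random_triad_test(rdm: RDM, triad, n_random: int = 1000, seed=0) -> TriadStats:
    """Compare a candidate triad's mean pairwise distance to random triads.

    Draws ``n_random`` distinct triads uniformly (without replacement) from
    all 3-subsets excluding the candidate; when ``n_random`` covers the whole
    population the test equals exhaustive enumeration. The t statistic is a
    one-sample t of the differences (triad mean - each random-triad mean)
    against zero, with a two-sided p.
    """
    items = rdm.items
    if len(items) < 6:
        raise ValueError("need at least 6 items")
    triad = tuple(triad)
    if not set(triad) <= set(items):
        raise ValueError("triad items must be in the RDM")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")

    all_triads = [t for t in itertools.combinations(range(len(items)), 3)
                  if set(items[i] for i in t) != set(triad)]
    rng = np.random.default_rng(seed)
    if n_random >= len(all_triads):
        sample = all_triads
    else:
        pick = rng.choice(len(all_triads), size=n_random, replace=False)
        sample = [all_triads[k] for k in pick]

    m = rdm.matrix
    triad_mean = rdm.pair_mean(triad)
    rand_means = np.array([(m[a, b] + m[a, c] + m[b, c]) / 3.0 for a, b, c in sample])
    diffs = triad_mean - rand_means
    m_diff = float(diffs.mean())
    if np.ptp(diffs) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(diffs, 0.0)
    return TriadStats(triad, triad_mean, float(rand_means.mean()), m_diff,
                      float(t), float(p), len(sample))


def select_triads(
    rdms: dict[str, RDM],
    candidates=None,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Rank candidate triads: semantically tight but shape-diverse.

    ``rdms`` must provide the three criterion RDMs under the keys
    ``no_instruction``, ``object`` and ``shape``. Each candidate triad is
    scored as mean no-instruction distance + mean object-category distance
    - lam * mean shape distance; lower scores rank first.
    """
    for key in ("no_instruction", "object", "shape"):
        if key not in rdms:
            raise ValueError(f"criterion RDM {key!r} missing")
    items = rdms["no_instruction"].items
    if candidates is None:
        candidates = list(itertools.combinations(items, 3))
    rows = []
    for triad in candidates:
        mn = rdms["no_instruction"].pair_mean(triad)
        mo = rdms["object"].pair_mean(triad)
        msh = rdms["shape"].pair_mean(triad)
        rows.append((tuple(triad), mn, mo, msh, mn + mo - lam * msh))
    out = pd.DataFrame(rows, columns=["triad", "mean_no_instruction",
                                      "mean_object", "mean_shape", "score"])
    return out.sort_values("score", ignore_index=True)
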