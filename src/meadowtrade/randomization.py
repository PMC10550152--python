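"""Block-constrained randomization tests for treatment contrasts.

Inference follows the randomization logic of a blocked field trial: under
the null hypothesis of no treatment effect, treatment labels are exchangeable
*within* blocks, so the null distribution of any contrast statistic is built
by repeatedly shuffling the treatment labels inside each block (preserving
every block's treatment multiset and hence the spatial structure) and
recomputing the statistic. Contrast statistics supported:

* difference in treatment means of a single indicator,
* difference in arithmetic group means (forage / plant / insect),
* difference in the composite weighted mean or weighted SD across all twelve
  indicators (50/25/25 weighting; see :mod:`meadowtrade.composite`).

The exceedance probability ``p_greater`` is the proportion of randomizations
in which the observed statistic is at least as large as the randomized one;
a contrast is called significant when ``p_greater`` falls in either tail
(default 0.05 per tail, i.e. a two-tailed level of 0.10). A two-sided
p-value with add-one correction is reported alongside. All shuffles for one
randomization are applied to whole rows, so cross-indicator correlation is
preserved; an exhaustive within-block enumeration is available as an exact
oracle on small designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composite import WeightScheme, default_weights, standardize_and_rescale
from .errors import ConfigurationError, DomainError, MeadowTradeError
from .indicators import GROUPS, INDICATORS

TIE_RULES = ("count_ties_as_exceed", "half_ties")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for Monte-Carlo randomization tests.

    ``tie_rule`` controls how randomized statistics exactly equal to the
    observed one enter ``p_greater``: ``count_ties_as_exceed`` (default;
    matches a "greater or equal" exceedance count) or ``half_ties`` (ties
    count one half, giving exact complementarity between the two orderings
    of a contrast). ``independent_indicator_shuffles`` re-shuffles labels
    per indicator instead of once per randomization (breaks cross-indicator
    correlation; off by default).
    """

    n_randomizations: int = 10_000
    seed: int = 0
    tie_rule: str = "count_ties_as_exceed"
    alpha_tails: float = 0.05
    independent_indicator_shuffles: bool = False

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ConfigurationError("n_randomizations must be >= 1")
        if not (0 < self.alpha_tails < 0.5):
            raise ConfigurationError("alpha_tails must lie in (0, 0.5)")
        if self.tie_rule not in TIE_RULES:
            raise ConfigurationError(f"tie_rule must be one of {TIE_RULES}")


@dataclass
class PermutationResult:
    """Observed statistic, Monte-Carlo null sample and tail probabilities."""

    treatment_a: str
    treatment_b: str
    statistic: str
    observed: float
    null_sample: np.ndarray
    p_greater: float
    p_two_sided: float
    significant: bool
    n_randomizations: int
    tie_rule: str
    note: str = ""


@dataclass
class ExactEnumerationResult:
    """Exact within-block enumeration of a contrast (oracle for Monte Carlo)."""

    treatment_a: str
    treatment_b: str
    statistic: str
    observed: float
    p_greater: float
    p_two_sided: float
    n_arrangements: int


# ---------------------------------------------------------------------------
# permutation machinery


def permute_within_blocks(
    plot_registry: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """One random reassignment of treatment labels, independently per block.

    The multiset of treatment labels inside every block is preserved.
    """
    labels = plot_registry["treatment"].to_numpy().copy()
    blocks = plot_registry["block"].to_numpy()
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    return pd.Series(labels, index=plot_registry.index, name="treatment")


def _codes(matrix: pd.DataFrame) -> tuple[list[str], np.ndarray, np.ndarray]:
    treatments = list(dict.fromkeys(matrix["treatment"]))
    code_map = {t: i for i, t in enumerate(treatments)}
    codes = matrix["treatment"].map(code_map).to_numpy(dtype=np.int64)
    blocks = matrix["block"].to_numpy()
    return treatments, codes, blocks


def _assignment_matrix(
    blocks: np.ndarray, codes: np.ndarray, n_rand: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_rand, n_plots) treatment codes, each row a within-block shuffle."""
    out = np.empty((n_rand, codes.size), dtype=np.int64)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        tiles = np.tile(codes[idx], (n_rand, 1))
        out[:, idx] = rng.permuted(tiles, axis=1)
    return out


def _treatment_means(X: np.ndarray, assignments: np.ndarray, n_treat: int) -> np.ndarray:
    """Per-treatment indicator means for every assignment.

    ``X`` is (n_plots, K); returns (n_rand, n_treat, K). Treatment counts are
    constant across assignments because shuffles conserve label multisets.
    """
    M = np.empty((assignments.shape[0], n_treat, X.shape[1]))
    for t in range(n_treat):
        mask = (assignments == t).astype(float)
        M[:, t, :] = (mask @ X) / mask.sum(axis=1, keepdims=True)
    return M


def _p_values(
    observed: float, null: np.ndarray, tie_rule: str
) -> tuple[float, float]:
    n = null.size
    if tie_rule == "count_ties_as_exceed":
        p_greater = float(np.count_nonzero(observed >= null)) / n
    else:
        gt = np.count_nonzero(observed > null)
        eq = np.count_nonzero(observed == null)
        p_greater = (gt + 0.5 * eq) / n
    p_two = (np.count_nonzero(np.abs(null) >= np.abs(observed)) + 1.0) / (n + 1.0)
    return p_greater, float(p_two)


def _finish(
    t_a: str,
    t_b: str,
    statistic: str,
    observed: float,
    null: np.ndarray,
    config: PermutationConfig,
    note: str = "",
) -> PermutationResult:
    p_greater, p_two = _p_values(observed, null, config.tie_rule)
    significant = p_greater < config.alpha_tails or p_greater > 1 - config.alpha_tails
    return PermutationResult(
        treatment_a=t_a,
        treatment_b=t_b,
        statistic=statistic,
        observed=float(observed),
        null_sample=null,
        p_greater=p_greater,
        p_two_sided=p_two,
        significant=significant,
        n_randomizations=config.n_randomizations,
        tie_rule=config.tie_rule,
        note=note,
    )


def _check_pair(treatments: list[str], t_a: str, t_b: str) -> None:
    for t in (t_a, t_b):
        if t not in treatments:
            raise MeadowTradeError(f"unknown treatment {t!r}; have {treatments}")


class _Engine:
    """Shared state for a set of contrasts on one matrix: the indicator value
    array, one observed and one null stack of per-treatment means."""

    def __init__(self, matrix: pd.DataFrame, config: PermutationConfig,
                 columns: tuple[str, ...] = INDICATORS):
        self.columns = [c for c in columns if c in matrix.columns]
        if not self.columns:
            raise MeadowTradeError("matrix has no indicator columns")
        self.treatments, codes, blocks = _codes(matrix)
        self.config = config
        X = matrix[self.columns].to_numpy(dtype=float)
        rng = np.random.default_rng(config.seed)
        nt = len(self.treatments)
        # The observed statistic rides along as row 0 of the same batched
        # mean computation as the null sample, so a shuffle that reproduces
        # the observed assignment yields a bitwise-identical statistic and
        # ties are detected exactly.
        if config.independent_indicator_shuffles:
            obs = np.empty((nt, X.shape[1]))
            null = np.empty((config.n_randomizations, nt, X.shape[1]))
            for k in range(X.shape[1]):
                A = _assignment_matrix(blocks, codes, config.n_randomizations, rng)
                A = np.vstack([codes[None, :], A])
                M = _treatment_means(X[:, [k]], A, nt)[:, :, 0]
                obs[:, k] = M[0]
                null[:, :, k] = M[1:]
            self.observed, self.null = obs, null
        else:
            A = _assignment_matrix(blocks, codes, config.n_randomizations, rng)
            A = np.vstack([codes[None, :], A])
            M = _treatment_means(X, A, nt)
            self.observed, self.null = M[0], M[1:]  # (T, K), (R, T, K)

    def col(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise MeadowTradeError(f"unknown indicator {name!r}") from None

    def tcode(self, t: str) -> int:
        _check_pair(self.treatments, t, t)
        return self.treatments.index(t)

    # statistic evaluators; M is (..., T, K)
    def indicator_diff(self, M: np.ndarray, a: int, b: int, k: int) -> np.ndarray:
        return M[..., a, k] - M[..., b, k]

    def group_diff(self, M: np.ndarray, a: int, b: int, ks: list[int]) -> np.ndarray:
        return M[..., a, ks].mean(axis=-1) - M[..., b, ks].mean(axis=-1)

    def wmean_diff(self, M: np.ndarray, a: int, b: int, w: np.ndarray) -> np.ndarray:
        return (M[..., a, :] - M[..., b, :]) @ w

    def wsd_diff(self, M: np.ndarray, a: int, b: int, w: np.ndarray) -> np.ndarray:
        mu = M @ w
        dev = M - mu[..., None]
        wsd = np.sqrt((dev**2) @ w)
        return wsd[..., a] - wsd[..., b]


def pairwise_indicator_test(
    matrix: pd.DataFrame,
    indicator: str,
    treatment_a: str,
    treatment_b: str,
    config: PermutationConfig | None = None,
) -> PermutationResult:
    """Randomization test of ``mean(A) - mean(B)`` for one indicator.

    The observed difference in treatment means is compared against the null
    sample obtained from within-block label shuffles. Affine per-column
    transforms (z-scoring, min-max rescaling) leave the p-values unchanged,
    so the matrix may be raw or rescaled.
    """
    config = config or PermutationConfig()
    eng = _Engine(matrix, config)
    a, b, k = eng.tcode(treatment_a), eng.tcode(treatment_b), eng.col(indicator)
    observed = float(eng.indicator_diff(eng.observed[None], a, b, k)[0])
    null = eng.indicator_diff(eng.null, a, b, k)
    return _finish(treatment_a, treatment_b, indicator, observed, null, config)


def group_average_test(
    matrix: pd.DataFrame,
    group: str,
    treatment_a: str,
    treatment_b: str,
    config: PermutationConfig | None = None,
) -> PermutationResult:
    """Randomization test on the difference in arithmetic group means."""
    config = config or PermutationConfig()
    if group not in GROUPS:
        raise MeadowTradeError(f"unknown indicator group {group!r}; have {sorted(GROUPS)}")
    eng = _Engine(matrix, config)
    ks = [eng.col(c) for c in GROUPS[group] if c in eng.columns]
    if not ks:
        raise MeadowTradeError(f"group {group!r} has no indicators in the matrix")
    a, b = eng.tcode(treatment_a), eng.tcode(treatment_b)
    observed = float(eng.group_diff(eng.observed[None], a, b, ks)[0])
    null = eng.group_diff(eng.null, a, b, ks)
    return _finish(treatment_a, treatment_b, f"group_mean_{group}", observed, null, config)


def composite_test(
    matrix: pd.DataFrame,
    scheme: WeightScheme | None = None,
    treatment_a: str = "",
    treatment_b: str = "",
    statistic: str = "weighted_mean",
    config: PermutationConfig | None = None,
) -> PermutationResult:
    """Randomization test on the composite weighted mean or weighted SD.

    ``matrix`` must be on the rescaled [0, 1] scale. The statistic is the
    difference (A minus B) of the composite computed over each treatment's
    per-indicator means. For ``weighted_sd`` a *lower* observed value means
    better performance (less spread across indicators, i.e. a weaker
    trade-off), noted on the result.
    """
    config = config or PermutationConfig()
    scheme = scheme or default_weights()
    if statistic not in ("weighted_mean", "weighted_sd"):
        raise MeadowTradeError(f"unknown composite statistic {statistic!r}")
    eng = _Engine(matrix, config)
    w = scheme.vector(tuple(eng.columns))
    a, b = eng.tcode(treatment_a), eng.tcode(treatment_b)
    fn = eng.wmean_diff if statistic == "weighted_mean" else eng.wsd_diff
    observed = float(fn(eng.observed[None], a, b, w)[0])
    null = fn(eng.null, a, b, w)
    note = "lower observed weighted_sd indicates better performance" if statistic == "weighted_sd" else ""
    return _finish(treatment_a, treatment_b, statistic, observed, null, config, note)


def exact_enumeration_test(
    matrix: pd.DataFrame,
    indicator: str,
    treatment_a: str,
    treatment_b: str,
    tie_rule: str = "count_ties_as_exceed",
    max_arrangements: int = 1_000_000,
) -> ExactEnumerationResult:
    """Exhaustive within-block enumeration of a single-indicator contrast.

    Enumerates every distinct assignment of treatment labels within each
    block (all blocks combined as a cartesian product, each arrangement
    equally likely) and returns exact tail probabilities. Serves as the
    oracle the Monte-Carlo test converges to. Raises on designs with more
    than ``max_arrangements`` arrangements — use the Monte-Carlo test there.
    """
    from sympy.utilities.iterables import multiset_permutations

    if tie_rule not in TIE_RULES:
        raise ConfigurationError(f"tie_rule must be one of {TIE_RULES}")
    treatments, codes, blocks = _codes(matrix)
    _check_pair(treatments, treatment_a, treatment_b)
    x = matrix[indicator].to_numpy(dtype=float) if indicator in matrix.columns else None
    if x is None:
        raise MeadowTradeError(f"unknown indicator {indicator!r}")

    block_ids = list(np.unique(blocks))
    block_idx = [np.flatnonzero(blocks == b) for b in block_ids]
    per_block = [list(multiset_permutations(list(codes[idx]))) for idx in block_idx]
    total = math.prod(len(p) for p in per_block)
    if total > max_arrangements:
        raise DomainError(
            f"exact enumeration infeasible: {total} arrangements > {max_arrangements}; "
            "use the Monte-Carlo test"
        )

    a, b = treatments.index(treatment_a), treatments.index(treatment_b)
    sum_a = x[codes == a].sum()
    sum_b = x[codes == b].sum()
    n_a, n_b = int((codes == a).sum()), int((codes == b).sum())
    observed = sum_a / n_a - sum_b / n_b

    stats = np.empty(total)
    assign = np.empty_like(codes)
    for i, combo in enumerate(itertools.product(*per_block)):
        for idx, arrangement in zip(block_idx, combo):
            assign[idx] = arrangement
        stats[i] = x[assign == a].mean() - x[assign == b].mean()
    p_greater, _ = _p_values(observed, stats, tie_rule)
    # exact two-sided probability: plain proportion, no add-one correction
    p_two = float(np.count_nonzero(np.abs(stats) >= np.abs(observed))) / total
    return ExactEnumerationResult(
        treatment_a=treatment_a,
        treatment_b=treatment_b,
        statistic=indicator,
        observed=float(observed),
        p_greater=p_greater,
        p_two_sided=p_two,
        n_arrangements=total,
    )


def run_full_contrast_table(
    matrix: pd.DataFrame,
    scheme: WeightScheme | None = None,
    config: PermutationConfig | None = None,
    rescale: bool = True,
) -> pd.DataFrame:
    """All ordered treatment pairs x (12 indicators + 3 group means + composite).

    For 4 treatments this is 12 pairs x 17 statistics = 204 rows. One pool of
    within-block shuffles (``config.n_randomizations`` of them) is shared by
    every contrast, so the table is deterministic under ``config.seed`` and
    the two orderings of a pair see complementary null samples.

    ``rescale=True`` (default) applies the canonical z-score + min-max chain
    first; single-indicator and group p-values are invariant to it, composite
    statistics require it.
    """
    config = config or PermutationConfig()
    scheme = scheme or default_weights()
    if matrix["treatment"].nunique() < 2:
        raise MeadowTradeError("contrast table needs at least two treatments")
    work = standardize_and_rescale(matrix) if rescale else matrix
    eng = _Engine(work, config)
    w = scheme.vector(tuple(eng.columns))
    group_ks = {g: [eng.col(c) for c in members if c in eng.columns]
                for g, members in GROUPS.items()}

    rows = []
    for t_a, t_b in itertools.permutations(eng.treatments, 2):
        a, b = eng.tcode(t_a), eng.tcode(t_b)
        stats: list[tuple[str, np.ndarray, np.ndarray]] = []
        for k, name in enumerate(eng.columns):
            stats.append((name, eng.indicator_diff(eng.observed[None], a, b, k),
                          eng.indicator_diff(eng.null, a, b, k)))
        for g, ks in group_ks.items():
            stats.append((f"group_mean_{g}", eng.group_diff(eng.observed[None], a, b, ks),
                          eng.group_diff(eng.null, a, b, ks)))
        stats.append(("weighted_mean", eng.wmean_diff(eng.observed[None], a, b, w),
                      eng.wmean_diff(eng.null, a, b, w)))
        stats.append(("weighted_sd", eng.wsd_diff(eng.observed[None], a, b, w),
                      eng.wsd_diff(eng.null, a, b, w)))
        for name, obs, null in stats:
            p_greater, p_two = _p_values(float(obs[0]), null, config.tie_rule)
            significant = (
                p_greater < config.alpha_tails or p_greater > 1 - config.alpha_tails
            )
            rows.append(
                {
                    "first_treatment": t_a,
                    "second_treatment": t_b,
                    "statistic": name,
                    "observed": float(obs[0]),
                    "p_greater": p_greater,
                    "p_two_sided": p_two,
                    "significant": significant,
                    "stars": "*" if significant else "",
                }
            )
    return pd.DataFrame(rows)
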