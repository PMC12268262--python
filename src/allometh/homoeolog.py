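"""Homoeolog expression bias and expression-level dominance (ELD).

A homoeolog quartet links one gene in each diploid progenitor genome (Ad,
Ai) with its two descendant homoeologs on the allotetraploid subgenomes
(At, Bt).  Two complementary classifications are computed per quartet:

* **Bias** — within a generation, is one homoeolog expressed > 2-fold above
  the other with t-test support?  The parental call contrasts the Ad gene
  (in Ad samples) against the Ai gene (in Ai samples, unpaired Welch t);
  the progeny call contrasts At against Bt within the same tetraploid
  libraries (paired t).  Transitions between generations fall into
  Parental Condition / No Bias in Progeny / Novel Bias in Progeny /
  Unbiased.

* **ELD** — the summed tetraploid expression t = At + Bt is compared with
  each parent (a = Ad, b = Ai) and the parents with each other; the sign
  pattern of the three relations maps onto the classic 12-subcategory
  framework (I-XII) grouped into additivity, ELD-A, ELD-B, transgressive
  up/down and no change.  "=" means t-test non-significance.  The
  triple-to-subcategory table ships as module data so numeral conventions
  can be edited without code change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ParameterError, RowError
from .expression import welch_t

QUARTET_COLUMNS = ("ad_gene", "ai_gene", "at_gene", "bt_gene")

#: (sign(t - a), sign(t - b), sign(a - b)) -> (subcategory, major class)
#: for every transitively consistent relation triple ("0" = non-significant)
ELD_PATTERN_TABLE: dict[tuple[int, int, int], tuple[str, str]] = {
    (0, 0, 0): ("none", "no_change"),
    (0, 1, 1): ("II", "ELD-A"),
    (0, -1, -1): ("XI", "ELD-A"),
    (1, 0, -1): ("IV", "ELD-B"),
    (-1, 0, 1): ("IX", "ELD-B"),
    (1, -1, -1): ("I", "additivity"),
    (-1, 1, 1): ("XII", "additivity"),
    (1, 1, -1): ("V", "transgressive_up"),
    (1, 1, 0): ("VI", "transgressive_up"),
    (1, 1, 1): ("VIII", "transgressive_up"),
    (-1, -1, -1): ("III", "transgressive_down"),
    (-1, -1, 0): ("VII", "transgressive_down"),
    (-1, -1, 1): ("X", "transgressive_down"),
}


@dataclass
class QuartetExpression:
    """Normalized expression of every quartet role, quartets x replicates.

    ``a``/``b`` hold diploid parent values (Ad/Ai samples); ``at``/``bt``
    hold the two tetraploid homoeologs, column-aligned to the same
    tetraploid libraries so paired contrasts are meaningful.
    """

    a: pd.DataFrame
    b: pd.DataFrame
    at: pd.DataFrame
    bt: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.a.index
        for name in ("b", "at", "bt"):
            if not getattr(self, name).index.equals(idx):
                raise ParameterError(f"quartet index mismatch between 'a' and {name!r}")
        if not self.at.columns.equals(self.bt.columns):
            raise ParameterError("at/bt must share tetraploid sample columns (paired design)")


def read_homoeolog_map(
    path: str | Path, annotation_ids: set[str] | None = None
) -> pd.DataFrame:
    """Read the 4-column quartet TSV; reject duplicated or unknown gene ids."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in QUARTET_COLUMNS if c not in table.columns]
    if missing:
        raise RowError(f"{path}: missing quartet column(s) {missing}")
    table = table[list(QUARTET_COLUMNS)]
    for col in QUARTET_COLUMNS:
        dup = table[col][table[col].duplicated()]
        if not dup.empty:
            raise RowError(f"{path}: duplicated {col} id {dup.iloc[0]!r}")
        if annotation_ids is not None:
            unknown = set(table[col]) - annotation_ids
            if unknown:
                raise RowError(f"{path}: {col} id {sorted(unknown)[0]!r} absent from annotation")
    flat = table.to_numpy().ravel()
    if len(set(flat)) != flat.size:
        raise RowError(f"{path}: a gene id appears in more than one quartet column")
    table.index = pd.RangeIndex(len(table), name="quartet")
    return table


def _paired_t(diff: np.ndarray) -> float:
    if np.var(diff) == 0:
        return 1.0 if diff.mean() == 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant inputs
        return float(stats.ttest_1samp(diff, 0.0).pvalue)


def _bias_state(log2fc: float, p: float, alpha: float, log_fc_cut: float) -> str:
    if p < alpha and abs(log2fc) >= log_fc_cut - 1e-9:
        return "A-bias" if log2fc > 0 else "B-bias"
    return "none"


def classify_bias(
    expr: QuartetExpression,
    alpha: float = 0.05,
    fc: float = 2.0,
    expressed: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Parental and progeny bias calls plus the transition category per quartet.

    log2FC is always A-side over B-side on log2(x + 0.5) values.  Quartets
    with ``expressed`` False are skipped (left out of the output).
    """
    cut = np.log2(fc)
    la, lb = np.log2(expr.a + 0.5), np.log2(expr.b + 0.5)
    lat, lbt = np.log2(expr.at + 0.5), np.log2(expr.bt + 0.5)
    rows = []
    keep = np.ones(len(expr.a), dtype=bool) if expressed is None else np.asarray(expressed)
    for i, q in enumerate(expr.a.index):
        if not keep[i]:
            continue
        a, b = la.iloc[i].to_numpy(), lb.iloc[i].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ParameterError("classify_bias requires >= 2 replicates per parent")
        fc_par = float(a.mean() - b.mean())
        p_par = welch_t(a, b)
        diff = lat.iloc[i].to_numpy() - lbt.iloc[i].to_numpy()
        if diff.size < 2:
            raise ParameterError("classify_bias requires >= 2 tetraploid replicates")
        fc_pro = float(diff.mean())
        p_pro = _paired_t(diff)
        s_par = _bias_state(fc_par, p_par, alpha, cut)
        s_pro = _bias_state(fc_pro, p_pro, alpha, cut)
        rows.append(
            {
                "quartet": q,
                "parental_log2FC": fc_par,
                "parental_p": p_par,
                "parental_state": s_par,
                "progeny_log2FC": fc_pro,
                "progeny_p": p_pro,
                "progeny_state": s_pro,
                "transition": bias_transition(s_par, s_pro),
            }
        )
    return pd.DataFrame(rows).set_index("quartet")


def bias_transition(parental: str, progeny: str) -> str:
    """Trichotomy of bias transitions between generations.

    Same non-none state -> ParentalCondition; parental bias lost ->
    NoBiasInProgeny; progeny bias absent from the parents (novel or
    reversed) -> NovelBiasInProgeny; neither biased -> Unbiased.
    """
    states = {"A-bias", "B-bias", "none"}
    if parental not in states or progeny not in states:
        raise ParameterError(f"unknown bias state ({parental!r}, {progeny!r})")
    if parental == "none" and progeny == "none":
        return "Unbiased"
    if parental == progeny:
        return "ParentalCondition"
    if progeny == "none":
        return "NoBiasInProgeny"
    return "NovelBiasInProgeny"


def _relation(x: np.ndarray, y: np.ndarray, alpha: float) -> int:
    """Sign of mean(x) - mean(y), or 0 when the Welch t-test is non-significant."""
    p = welch_t(x, y)
    if p >= alpha:
        return 0
    return 1 if x.mean() > y.mean() else -1


def eld_pattern(r_ta: int, r_tb: int, r_ab: int) -> tuple[str, str, bool]:
    """Map a relation triple to (subcategory, major class, inconsistent flag).

    Transitively impossible triples (e.g. t = a, a = b, t > b) are resolved
    deterministically in favor of the (a vs b) relation, then (t vs a), and
    flagged.
    """
    hit = ELD_PATTERN_TABLE.get((r_ta, r_tb, r_ab))
    if hit is not None:
        return hit[0], hit[1], False
    if r_ab == 0 and r_ta == 0:
        resolved = (0, 0, 0)
    elif r_ab == 0:
        resolved = (r_ta, r_ta, 0)
    elif r_ta == 0:
        resolved = (0, r_ab, r_ab)
    else:
        resolved = (r_ta, r_ab, r_ab)
    sub, major = ELD_PATTERN_TABLE[resolved]
    return sub, major, True


def classify_eld(
    expr: QuartetExpression,
    alpha: float = 0.05,
    expressed: Sequence[bool] | None = None,
    adjust: bool = False,
    equiv_fold: float = 1.0,
) -> pd.DataFrame:
    """ELD call per quartet from the (t vs a), (t vs b), (a vs b) relations.

    t is the per-replicate sum At + Bt within the tetraploid libraries.
    Two optional guards tighten the "=" relation beyond raw t-test
    non-significance (three raw tests per quartet mislabel
    ~1 - (1-alpha)^3 of truly unchanged pairs by chance):

    * ``adjust=True`` Benjamini-Hochberg corrects the relation p-values
      jointly across quartets before the alpha gate;
    * ``equiv_fold`` > 1 additionally calls "=" whenever the mean ratio is
      below that fold, so significance alone cannot separate near-equal
      levels.  Both default off.
    """
    from statsmodels.stats.multitest import multipletests

    if equiv_fold < 1.0:
        raise ParameterError(f"equiv_fold must be >= 1, got {equiv_fold}")
    t_mat = expr.at + expr.bt
    keep = np.ones(len(expr.a), dtype=bool) if expressed is None else np.asarray(expressed)
    quartets, pvals, signs, folds = [], [], [], []
    for i, q in enumerate(expr.a.index):
        if not keep[i]:
            continue
        a = expr.a.iloc[i].to_numpy(dtype=float)
        b = expr.b.iloc[i].to_numpy(dtype=float)
        t = t_mat.iloc[i].to_numpy(dtype=float)
        quartets.append(q)
        for x, y in ((t, a), (t, b), (a, b)):
            pvals.append(welch_t(x, y))
            signs.append(1 if x.mean() > y.mean() else (-1 if x.mean() < y.mean() else 0))
            hi, lo = max(x.mean(), y.mean()), min(x.mean(), y.mean())
            folds.append(np.inf if lo <= 0 else hi / lo)
    pvals = np.asarray(pvals)
    if adjust and pvals.size:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    for j, q in enumerate(quartets):
        r = [
            signs[3 * j + k]
            if pvals[3 * j + k] < alpha and folds[3 * j + k] >= equiv_fold
            else 0
            for k in range(3)
        ]
        sub, major, inconsistent = eld_pattern(*r)
        rows.append(
            {
                "quartet": q,
                "r_ta": r[0],
                "r_tb": r[1],
                "r_ab": r[2],
                "subcategory": sub,
                "major": major,
                "inconsistent": inconsistent,
            }
        )
    return pd.DataFrame(rows).set_index("quartet")


#: homoeolog-modification patterns for the ELD cause decomposition
DECOMPOSITION_PATTERNS = (
    "A_up_only",
    "A_down_only",
    "B_up_only",
    "B_down_only",
    "both_up",
    "both_down",
    "mixed",
    "neither",
)


def _pattern(a_status: str, b_status: str) -> str:
    if a_status == "ns" and b_status == "ns":
        return "neither"
    if b_status == "ns":
        return f"A_{a_status}_only"
    if a_status == "ns":
        return f"B_{b_status}_only"
    if a_status == b_status:
        return f"both_{a_status}"
    return "mixed"


def eld_cause_decomposition(
    eld_calls: pd.DataFrame,
    deg_a: Mapping | pd.Series,
    deg_b: Mapping | pd.Series,
) -> pd.DataFrame:
    """Count homoeolog-modification patterns within each ELD major class.

    ``deg_a``/``deg_b`` give the per-quartet DE status ("up"/"down"/"ns")
    of the At-vs-Ad and Bt-vs-Ai progeny-vs-parent contrasts.  Counts over
    all patterns sum to the number of quartets per class.
    """
    deg_a, deg_b = pd.Series(deg_a), pd.Series(deg_b)
    pat = [
        _pattern(deg_a.get(q, "ns"), deg_b.get(q, "ns")) for q in eld_calls.index
    ]
    table = (
        pd.DataFrame({"major": eld_calls["major"].to_numpy(), "pattern": pat})
        .groupby(["major", "pattern"])
        .size()
        .rename("count")
        .reset_index()
    )
    return table


def normalize_quartet_expression(
    counts: Mapping[str, pd.DataFrame],
    gene_lengths: pd.Series | Mapping[str, float],
    quartets: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> QuartetExpression:
    """FPKM-normalize all species onto the homoeolog-matched gene universe.

    Cross-species TMM factors are estimated on a quartet-level matrix
    (tetraploid entries are At + Bt sums) because TMM assumes a shared,
    majority-non-changing gene set; library sizes are the full per-sample
    count totals, scaled by those factors inside the FPKM denominator.
    ``counts`` maps species ("Ad", "Ai", "Ah") to gene x sample matrices.
    """
    from .expression import tmm_factors  # local import avoids a cycle at import time

    lengths = pd.Series(gene_lengths)
    sp_samples = {
        sp: list(sample_sheet.loc[sample_sheet["species"] == sp, "sample_id"])
        for sp in ("Ad", "Ai", "Ah")
    }
    matched = pd.DataFrame(index=quartets.index)
    for sid in sp_samples["Ad"]:
        matched[sid] = counts["Ad"][sid].reindex(quartets["ad_gene"]).to_numpy()
    for sid in sp_samples["Ai"]:
        matched[sid] = counts["Ai"][sid].reindex(quartets["ai_gene"]).to_numpy()
    for sid in sp_samples["Ah"]:
        matched[sid] = (
            counts["Ah"][sid].reindex(quartets["at_gene"]).to_numpy()
            + counts["Ah"][sid].reindex(quartets["bt_gene"]).to_numpy()
        )
    factors = tmm_factors(matched)
    lib = {
        sid: float(counts[sp][sid].sum())
        for sp, sids in sp_samples.items()
        for sid in sids
    }

    def role_fpkm(species: str, gene_col: str) -> pd.DataFrame:
        genes = quartets[gene_col]
        glen = lengths.reindex(genes).to_numpy(dtype=float)
        out = {}
        for sid in sp_samples[species]:
            vals = counts[species][sid].reindex(genes).to_numpy(dtype=float)
            out[sid] = vals * 1e9 / (glen * lib[sid] * factors[sid])
        return pd.DataFrame(out, index=quartets.index)

    return QuartetExpression(
        a=role_fpkm("Ad", "ad_gene"),
        b=role_fpkm("Ai", "ai_gene"),
        at=role_fpkm("Ah", "at_gene"),
        bt=role_fpkm("Ah", "bt_gene"),
    )


def binomial_direction_test(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k successes of n.

    For the symmetric null p0 = 0.5 this is min(1, 2 x the tail beyond and
    including k); general p0 delegates to the exact minlike method.
    """
    if n <= 0:
        raise ParameterError("binomial_direction_test: n must be > 0")
    if not 0 <= k <= n:
        raise ParameterError(f"k={k} outside [0, {n}]")
    if p0 == 0.5:
        if k >= n / 2:
            tail = stats.binom.sf(k - 1, n, 0.5)
        else:
            tail = stats.binom.cdf(k, n, 0.5)
        return float(min(1.0, 2.0 * tail))
    return float(stats.binomtest(k, n, p0).pvalue)
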