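"""Univariate class comparison: Kruskal-Wallis, Dunn post hoc, compact
letter display.

Reproduces the superscript-letter structure of class summary tables: each
feature is tested across the six classes with the tie-corrected
Kruskal-Wallis H, followed by Dunn's pairwise z-tests on the pooled ranks
with Holm adjustment, and the adjusted p-value matrix is converted to
letters such that two classes share a letter if and only if they are not
significantly different at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .blocks import FeatureBlock


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float


def kruskal_wallis(groups: list) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        raise ValueError("all pooled values are identical; H is undefined")
    H, p = sps.kruskal(*groups)
    return KWResult(H=float(H), df=len(groups) - 1, p=float(p))


@dataclass
class PosthocMatrix:
    """Symmetric matrix of adjusted pairwise p-values (diagonal = 1)."""

    p: pd.DataFrame
    adjustment: str

    @property
    def group_names(self) -> list[str]:
        return list(self.p.index)


def dunn_posthoc(groups: list, names: list[str] | None = None,
                 adjust: str = "holm") -> PosthocMatrix:
    """Dunn's post hoc z-tests on pooled tie-corrected ranks.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    where ``T = sum(t^3 - t)`` over tie groups; two-sided normal p-values
    are adjusted across all pairs (``holm`` by default, ``none`` for raw).
    """
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values each")
    names = list(names) if names is not None else [f"g{i}" for i in range(k)]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("all pooled values are identical")
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    raw = np.ones((k, k))
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            pairs.append((i, j))
            pvals.append(p)
    if adjust == "none":
        adj = np.asarray(pvals)
    else:
        adj = multipletests(pvals, method=adjust)[1]
    for (i, j), p in zip(pairs, adj):
        raw[i, j] = raw[j, i] = min(float(p), 1.0)
    return PosthocMatrix(p=pd.DataFrame(raw, index=names, columns=names),
                         adjustment=adjust)


@dataclass
class LetterDisplay:
    """Class -> letter string; classes sharing a letter do not differ
    significantly at the display's alpha."""

    letters: dict[str, str]
    alpha: float

    def __getitem__(self, name: str) -> str:
        return self.letters[name]


def letter_display(ph: PosthocMatrix, alpha: float = 0.05) -> LetterDisplay:
    """Compact letter display by insert-and-absorb.

    Starts from one letter covering all classes; every significantly
    different pair splits each letter containing both, and letters that
    become subsets of others are absorbed.  Letters are assigned a..z in
    order of first use following the class order of the matrix, so the
    output is deterministic.
    """
    names = ph.group_names
    k = len(names)
    sig = [(i, j) for i in range(k) for j in range(i + 1, k)
           if ph.p.iat[i, j] < alpha]
    groups: list[set[int]] = [set(range(k))]
    for i, j in sig:
        new_groups: list[set[int]] = []
        for g in groups:
            if i in g and j in g:
                new_groups.extend((g - {i}, g - {j}))
            else:
                new_groups.append(g)
        # absorb: drop any group contained in another
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= kept for kept in groups):
                groups.append(g)
    # deterministic letter order: by first (lowest-index) member, then size
    groups.sort(key=lambda g: (min(g), -len(g)))
    letters = {name: "" for name in names}
    for letter_idx, g in enumerate(groups):
        ch = chr(ord("a") + letter_idx)
        for member in sorted(g):
            letters[names[member]] += ch
    return LetterDisplay(letters=letters, alpha=alpha)


def compare_classes(block: FeatureBlock, alpha: float = 0.05,
                    adjust: str = "holm") -> pd.DataFrame:
    """Per-feature class comparison table: H, df, p and one letter column
    per class — the machine twin of a printed summary table's superscripts.

    Features whose pooled values are all identical (e.g. a band absent in
    every class) are reported with NaN statistics and empty letters.
    """
    class_order = list(dict.fromkeys(block.labels))
    rows = []
    for feat in block.feature_names:
        groups = [block.data.loc[block.labels == c, feat].to_numpy() for c in class_order]
        row: dict = {"feature": feat}
        try:
            kw = kruskal_wallis(groups)
            ld = letter_display(dunn_posthoc(groups, names=class_order, adjust=adjust), alpha=alpha)
            row.update(H=kw.H, df=kw.df, p=kw.p)
            row.update({f"letter_{c}": ld[c] for c in class_order})
        except ValueError:
            row.update(H=np.nan, df=len(class_order) - 1, p=np.nan)
            row.update({f"letter_{c}": "" for c in class_order})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
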