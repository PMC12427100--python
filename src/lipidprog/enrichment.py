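"""Over-representation analysis of lipid characteristics by Fisher's exact test.

Each characteristic level (a lipid class, the ether-linked flag, a chain
length or double-bond bin, or a user-supplied gene set) is crossed with a
selected species/gene set to give the 2x2 table

    a = in category & selected      b = in category & not selected
    c = not in category & selected  d = neither

The two-sided p-value uses the point-probability convention: sum the
hypergeometric probabilities of every table with the same margins whose
point probability does not exceed that of the observed table.  The tail
sum is accumulated in log space, so a finite log10 p-value is reported
even when the p-value underflows double precision — the regime usually
printed as "< 2.2e-16".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

#: conventional display floor: .Machine$double.eps in IEEE doubles
P_DISPLAY_FLOOR = 2.2e-16

# relative tolerance when comparing point probabilities (matches R / scipy)
_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    log10_p: float

    @property
    def p_display(self) -> str:
        if self.p_value < P_DISPLAY_FLOOR:
            return "< 2.2e-16"
        return f"{self.p_value:.3g}"


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test for one 2x2 table.

    Returns the sample (cross-product) odds ratio ``a*d / (b*c)`` — ``inf``
    when ``b*c == 0`` with ``a*d > 0``, ``nan`` when both products vanish —
    together with the two-sided p-value and its log10 computed in log space.
    """
    counts = (a, b, c, d)
    if any(v < 0 or v != int(v) for v in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(v) for v in counts)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("empty 2x2 table")

    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)

    # hypergeometric over tables with fixed margins: X = count in cell a
    category, selected = a + b, a + c
    lo = max(0, selected - (c + d))
    hi = min(category, selected)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n_total, category, selected)
    obs = logpmf[a - lo]
    mask = logpmf <= obs + np.log(_REL_TOL)
    logp = min(0.0, float(logsumexp(logpmf[mask])))
    return FisherResult(odds_ratio=float(odds), p_value=float(np.exp(logp)),
                        log10_p=logp / np.log(10.0))


def _enrich_one_set(
    universe: pd.DataFrame,
    selected: set[str],
    direction: str,
    characteristics: Iterable[str],
    alpha: float,
) -> list[dict]:
    all_ids = set(universe.index)
    extra = selected - all_ids
    if extra:
        raise ValueError(f"selected species outside universe: {sorted(extra)[:5]}")
    if not selected:
        logger.warning("empty %r set: all enrichment p-values are 1", direction)
    rows = []
    n_universe = len(all_ids)
    n_sel = len(selected)
    for char in characteristics:
        for level, members in universe.groupby(char).groups.items():
            cat = set(members)
            a = len(cat & selected)
            b = len(cat) - a
            c = n_sel - a
            d = n_universe - a - b - c
            res = fisher_exact_2x2(a, b, c, d)
            rows.append(
                {
                    "characteristic": char,
                    "level": level,
                    "direction": direction,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                    "log10_p": res.log10_p,
                    "p_display": res.p_display,
                    "enriched": bool(res.p_value < alpha),
                }
            )
    return rows


DEFAULT_CHARACTERISTICS = ("class", "ether_linked", "chain_bin", "db_bin")


def enrich_characteristics(
    universe: pd.DataFrame,
    sig_up: set[str],
    sig_down: set[str],
    alpha: float = 0.05,
    characteristics: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fisher over-representation of each characteristic level in the
    up- and down-regulated sets.

    ``universe`` is a characteristic table (see
    :func:`lipidprog.nomenclature.characteristic_table`) over *all tested*
    species — everything surviving preprocessing, not everything ever
    detected.  Rows are returned for every level and both directions;
    ``enriched`` flags p < alpha, with the odds ratio telling over
    (> 1) from under (< 1) representation.
    """
    if characteristics is None:
        characteristics = [c for c in DEFAULT_CHARACTERISTICS if c in universe.columns]
    rows = []
    for direction, sel in (("up", set(sig_up)), ("down", set(sig_down))):
        rows += _enrich_one_set(universe, sel, direction, characteristics, alpha)
    return pd.DataFrame(rows)


def enrich_survival_direction(
    screen: pd.DataFrame,
    universe: pd.DataFrame,
    alpha: float = 0.05,
    characteristics: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of characteristics among detrimental / beneficial lipids.

    ``screen`` is the survival screen table (one row per lipid with
    ``feature_id``, ``hr``, ``logrank_p``, ``direction``); species with
    log-rank p < 0.05 and HR > 1 form the detrimental set, HR < 1 the
    beneficial set.
    """
    if characteristics is None:
        characteristics = [c for c in DEFAULT_CHARACTERISTICS if c in universe.columns]
    in_universe = screen["feature_id"].isin(universe.index)
    screen = screen[in_universe]
    detrimental = set(screen.loc[screen["direction"] == "detrimental", "feature_id"])
    beneficial = set(screen.loc[screen["direction"] == "beneficial", "feature_id"])
    rows = []
    for direction, sel in (("detrimental", detrimental), ("beneficial", beneficial)):
        rows += _enrich_one_set(universe, sel, direction, characteristics, alpha)
    return pd.DataFrame(rows)


def enrich_gene_sets(
    selected_genes: set[str],
    universe_genes: set[str],
    gene_sets: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher over-representation of user-supplied (GMT) gene sets.

    Gene sets are clipped to the universe; genes outside the universe are
    ignored.  Same 2x2 construction and two-sided test as the lipid
    characteristics.
    """
    selected = set(selected_genes) & set(universe_genes)
    rows = []
    for name, members in gene_sets.items():
        cat = set(members) & set(universe_genes)
        a = len(cat & selected)
        b = len(cat) - a
        c = len(selected) - a
        d = len(universe_genes) - a - b - c
        res = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {
                "gene_set": name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
                "log10_p": res.log10_p,
                "p_display": res.p_display,
                "enriched": bool(res.p_value < alpha),
            }
        )
    return pd.DataFrame(rows)
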