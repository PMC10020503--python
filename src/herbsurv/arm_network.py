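"""Association-rule mining and network analysis of CHM co-prescriptions.

The counting unit (a *transaction*) is one patient-day prescription event:
all distinct CHM products dispensed to one patient on one date.  Rule
statistics follow the standard market-basket definitions on the percent
scale:

    support(X,Y) % = 100 * freq(X and Y) / n_total
    confidence(X -> Y) % = 100 * freq(X and Y) / freq(X)
    p(Y) % = 100 * freq(Y) / n_total
    lift = confidence(X -> Y) % / p(Y) %

Lift is symmetric in X and Y; the printed rule direction puts the product
with the smaller marginal frequency on the left-hand side, which maximises
confidence.  Only pairs (2-itemsets) are mined; with catalogs of this size
exhaustive pair counting is trivial and no Apriori pruning is needed.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention used for table rendering."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransactionSet:
    """Patient-day transactions with their product sets."""

    transactions: tuple[tuple[str, str, frozenset], ...]  # (tid, patient, products)
    n_total: int

    def product_sets(self):
        return [t[2] for t in self.transactions]


@dataclass(frozen=True)
class RulePair:
    """One directed co-prescription rule X -> Y with its statistics."""

    x: str
    y: str
    freq_x: int
    freq_y: int
    freq_xy: int
    support_pct: float
    confidence_pct: float
    p_y_pct: float
    lift: float


def build_transactions(chm_prescriptions: pd.DataFrame) -> TransactionSet:
    """Group CHM rows into patient-day transactions.

    The same product dispensed twice on one day counts once in that
    transaction.
    """
    if chm_prescriptions is None or len(chm_prescriptions) == 0:
        return TransactionSet((), 0)
    df = chm_prescriptions
    if "class" in df.columns:
        df = df.loc[df["class"] == "CHM"]
    date_str = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    keys = list(zip(df["patient_id"].astype(str), date_str))
    groups: dict[tuple[str, str], set] = {}
    for key, prod in zip(keys, df["product_code"].astype(str)):
        groups.setdefault(key, set()).add(prod)
    txns = tuple(
        (f"{pid}:{d}", pid, frozenset(prods))
        for (pid, d), prods in sorted(groups.items())
    )
    return TransactionSet(txns, len(txns))


def rule_stats(
    freq_x: int, freq_y: int, freq_xy: int, n_total: int
) -> tuple[float, float, float]:
    """(support %, confidence %, lift) from marginal and joint transaction
    counts; full precision (rendering rounds separately)."""
    if n_total <= 0 or freq_x <= 0 or freq_y <= 0:
        raise DataError("rule_stats: zero denominator")
    if not (0 <= freq_xy <= min(freq_x, freq_y) <= n_total):
        raise DataError("rule_stats: inconsistent frequencies")
    support = 100.0 * freq_xy / n_total
    confidence = 100.0 * freq_xy / freq_x
    p_y = 100.0 * freq_y / n_total
    return support, confidence, confidence / p_y


def orient_rule(a: str, b: str, freq_a: int, freq_b: int) -> tuple[str, str]:
    """Antecedent = the product with the smaller marginal frequency (ties
    broken lexicographically), which maximises the rule's confidence."""
    if freq_a <= 0 or freq_b <= 0:
        raise DataError("orient_rule: frequencies must be positive")
    if freq_a < freq_b or (freq_a == freq_b and a <= b):
        return a, b
    return b, a


def pair_counts(ts: TransactionSet) -> tuple[Counter, Counter]:
    """Marginal and unordered-pair joint transaction counts."""
    marginal: Counter = Counter()
    joint: Counter = Counter()
    for _, _, prods in ts.transactions:
        items = sorted(prods)
        marginal.update(items)
        joint.update(itertools.combinations(items, 2))
    return marginal, joint


def _make_rule(a, b, marginal, joint, n_total) -> RulePair:
    fxy = joint[tuple(sorted((a, b)))]
    x, y = orient_rule(a, b, marginal[a], marginal[b])
    support, conf, lift = rule_stats(marginal[x], marginal[y], fxy, n_total)
    return RulePair(x, y, marginal[x], marginal[y], fxy, support, conf,
                    100.0 * marginal[y] / n_total, lift)


def top_rules(
    ts: TransactionSet, k: int = 5, min_freq_xy: int = 1
) -> list[RulePair]:
    """All product pairs ranked by joint frequency (then support, lift,
    lexicographic order); the top ``k`` returned as oriented rules."""
    if ts.n_total == 0:
        raise DataError("empty transaction set")
    marginal, joint = pair_counts(ts)
    rules = [
        _make_rule(a, b, marginal, joint, ts.n_total)
        for (a, b), f in joint.items()
        if f >= min_freq_xy
    ]
    rules.sort(key=lambda r: (-r.freq_xy, -r.support_pct, -r.lift, r.x, r.y))
    return rules[:k]


def dosage(product: str, chm_prescriptions: pd.DataFrame) -> float:
    """Total dispensed amount in grams attributed to a product:
    mean daily dose x mean prescription duration x prescription count."""
    df = chm_prescriptions
    if "class" in df.columns:
        df = df.loc[df["class"] == "CHM"]
    rows = df.loc[df["product_code"].astype(str) == str(product)]
    if len(rows) == 0:
        raise DataError(f"product {product!r} absent from prescriptions")
    return float(rows["daily_dose_g"].mean() * rows["days"].mean() * len(rows))


@dataclass
class CoPrescriptionGraph:
    """Undirected co-prescription network with component cluster labels."""

    graph: nx.Graph

    @property
    def clusters(self) -> dict[str, int]:
        return nx.get_node_attributes(self.graph, "cluster_id")

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edge_list_json(self, path) -> None:
        payload = {
            "nodes": [
                {"id": n, **{k: v for k, v in d.items()}}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [
                {"source": u, "target": v, **{k: val for k, val in d.items()}}
                for u, v, d in self.graph.edges(data=True)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def build_graph(
    rules: list[RulePair],
    chm_prescriptions: pd.DataFrame | None = None,
    node_min_freq: int = 1,
    edge_min_support_pct: float = 0.0,
) -> CoPrescriptionGraph:
    """Build the co-prescription network from mined rules.

    Nodes carry product kind, prescription frequency, and total dosage
    (when prescription rows are supplied); edges carry support, lift and
    joint frequency; ``cluster_id`` labels connected components, numbered
    by decreasing component size (ties broken by smallest node label).
    """
    g = nx.Graph()
    kind_map: dict[str, str] = {}
    if chm_prescriptions is not None and len(chm_prescriptions):
        df = chm_prescriptions
        if "class" in df.columns:
            df = df.loc[df["class"] == "CHM"]
        kind_map = (
            df.drop_duplicates("product_code")
            .set_index("product_code")["product_kind"]
            .to_dict()
        )
    for rule in rules:
        if rule.support_pct < edge_min_support_pct:
            continue
        for code, freq in ((rule.x, rule.freq_x), (rule.y, rule.freq_y)):
            if freq < node_min_freq:
                continue
            if code not in g:
                attrs = {"freq": int(freq), "kind": kind_map.get(code, "unknown")}
                if chm_prescriptions is not None and len(chm_prescriptions):
                    try:
                        attrs["dosage_g"] = dosage(code, chm_prescriptions)
                    except DataError:
                        pass
                g.add_node(code, **attrs)
        if rule.x in g and rule.y in g:
            g.add_edge(rule.x, rule.y,
                       support_pct=rule.support_pct,
                       lift=rule.lift,
                       freq_xy=int(rule.freq_xy))
    if g.number_of_nodes() == 0:
        log.warning("thresholds excluded every node; empty graph")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    for cid, comp in enumerate(comps, start=1):
        for node in comp:
            g.nodes[node]["cluster_id"] = cid
    return CoPrescriptionGraph(g)


def rules_table(
    rules: list[RulePair],
    chm_prescriptions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Render mined rules in the published table layout (two-decimal
    half-up rounding for percentages and lift; dosages to whole grams)."""
    rows = []
    for r in rules:
        row = {
            "lhs": r.x, "rhs": r.y,
            "freq_x": r.freq_x, "freq_y": r.freq_y, "freq_xy": r.freq_xy,
            "support_pct": round_half_up(r.support_pct),
            "confidence_pct": round_half_up(r.confidence_pct),
            "lift": round_half_up(r.lift),
        }
        if chm_prescriptions is not None and len(chm_prescriptions):
            for side, code in (("x", r.x), ("y", r.y)):
                try:
                    row[f"dosage_{side}_g"] = int(round(dosage(code, chm_prescriptions)))
                except DataError:
                    row[f"dosage_{side}_g"] = None
        rows.append(row)
    return pd.DataFrame(rows)
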