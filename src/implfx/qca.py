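"""Qualitative comparative analysis: subset relations and Boolean minimization.

Necessity and sufficiency are measured as consistency/coverage of fuzzy
subset relations (pointwise minima of memberships); sufficient
configurations are minimized with Quine-McCluskey prime implicants over the
positively coded truth-table rows. Only the conservative (complex) solution
is produced: remainder rows are never used as counterfactuals.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datasets import QCADataset
from .errors import ConfigurationError, StructuralError, UndefinedResultError


def _term_key(term):
    return tuple(2 if v is None else v for v in term)


LN19 = float(np.log(19.0))


# ---------------------------------------------------------------------------
# Boolean expressions ("A*~B + C") — used for planted solutions and reports
# ---------------------------------------------------------------------------

def parse_expression(text: str, names: list[str] | None = None):
    """Parse a sum-of-products style Boolean expression.

    Grammar: OR ``+``, AND ``*``, NOT ``~`` (prefix), parentheses, condition
    names matching ``[A-Za-z_][A-Za-z0-9_]*``. Returns a nested-tuple AST.
    """
    tokens = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "+*~()":
            tokens.append(ch)
            i += 1
        elif ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(text[i:j])
            i = j
        else:
            raise ConfigurationError(f"unexpected character {ch!r} in expression {text!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise ConfigurationError(f"malformed expression {text!r}")
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() == "+":
            take("+")
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_not()
        while peek() == "*":
            take("*")
            node = ("and", node, parse_not())
        return node

    def parse_not():
        if peek() == "~":
            take("~")
            return ("not", parse_not())
        if peek() == "(":
            take("(")
            node = parse_or()
            take(")")
            return node
        tok = take()
        if tok in "+*()~":
            raise ConfigurationError(f"malformed expression {text!r}")
        if names is not None and tok not in names:
            raise ConfigurationError(f"unknown condition {tok!r} in expression {text!r}")
        return ("var", tok)

    node = parse_or()
    if pos != len(tokens):
        raise ConfigurationError(f"trailing tokens in expression {text!r}")
    return node


def evaluate_expression(node, memberships: dict) -> np.ndarray:
    """Fuzzy evaluation: OR = max, AND = min, NOT = 1 - x."""
    kind = node[0]
    if kind == "var":
        return np.asarray(memberships[node[1]], dtype=float)
    if kind == "not":
        return 1.0 - evaluate_expression(node[1], memberships)
    a = evaluate_expression(node[1], memberships)
    b = evaluate_expression(node[2], memberships)
    return np.maximum(a, b) if kind == "or" else np.minimum(a, b)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationAnchors:
    """Direct-method anchors on the raw scale.

    Must be strictly monotone: increasing for a condition where larger raw
    values mean more membership, decreasing for a negated condition.
    """

    full_nonmembership: float
    crossover: float
    full_membership: float

    def __post_init__(self):
        a, c, b = self.full_nonmembership, self.crossover, self.full_membership
        if not (a < c < b or a > c > b):
            raise ConfigurationError(
                "calibration anchors must be strictly monotone: "
                f"got ({a}, {c}, {b})"
            )


def calibrate(raw, anchors: CalibrationAnchors) -> np.ndarray:
    """Piecewise-logistic membership: anchors map to 0.05 / 0.5 / 0.95.

    Strictly monotone in the raw score, so rank order is preserved.
    """
    x = np.asarray(raw, dtype=float)
    a, c, b = anchors.full_nonmembership, anchors.crossover, anchors.full_membership
    k_low = LN19 / (c - a)   # scale on the full-nonmembership side
    k_high = LN19 / (b - c)  # scale on the full-membership side
    on_a_side = (x - c) * (a - c) > 0
    k = np.where(on_a_side, k_low, k_high)
    return 1.0 / (1.0 + np.exp(-k * (x - c)))


# ---------------------------------------------------------------------------
# subset relations
# ---------------------------------------------------------------------------

class SetMeasure(NamedTuple):
    consistency: float
    coverage: float


def _min_sums(X, Y):
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise StructuralError("membership vectors must be 1-d, equal length >= 1")
    return float(np.minimum(x, y).sum()), float(x.sum()), float(y.sum())


def necessity(X, Y) -> SetMeasure:
    """Consistency of X as a necessary condition for Y: sum min(x,y) / sum y."""
    s_min, s_x, s_y = _min_sums(X, Y)
    if s_y == 0:
        raise UndefinedResultError("necessity undefined: outcome has zero total membership")
    cov = s_min / s_x if s_x > 0 else float("nan")
    return SetMeasure(consistency=s_min / s_y, coverage=cov)


def sufficiency(X, Y) -> SetMeasure:
    """Consistency of X as a sufficient condition for Y: sum min(x,y) / sum x."""
    s_min, s_x, s_y = _min_sums(X, Y)
    if s_x == 0:
        raise UndefinedResultError("sufficiency undefined: condition has zero total membership")
    cov = s_min / s_y if s_y > 0 else float("nan")
    return SetMeasure(consistency=s_min / s_x, coverage=cov)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """One row per observed configuration, with sufficiency consistency and
    the outcome coding used for minimization."""

    rows: pd.DataFrame  # columns: <conditions...>, n, consistency, outcome, contradictory, remainder
    conditions: list[str]
    dataset: QCADataset
    freq_cutoff: int
    cons_cutoff: float
    n_excluded: int = 0  # cases with a membership exactly 0.5


def _config_membership(data: QCADataset, bits) -> np.ndarray:
    m = data.memberships.to_numpy(dtype=float)
    parts = np.where(np.asarray(bits, dtype=bool)[None, :], m, 1.0 - m)
    return parts.min(axis=1)


def build_truth_table(
    data: QCADataset, freq_cutoff: int = 1, cons_cutoff: float = 0.8
) -> TruthTable:
    """Assign each case to the configuration of its strongest membership
    (per-condition membership > 0.5) and code rows by sufficiency consistency.

    Rows with fewer than ``freq_cutoff`` cases are remainders; rows at or
    above ``cons_cutoff`` are coded 1, the rest 0. Crisp rows whose cases
    disagree on the outcome are flagged contradictory. Cases with any
    membership exactly 0.5 have no unique configuration and are excluded
    with a warning.
    """
    if freq_cutoff < 1:
        raise ConfigurationError("freq_cutoff must be >= 1")
    if not (0.5 < cons_cutoff <= 1.0):
        raise ConfigurationError("cons_cutoff must lie in (0.5, 1]")
    m = data.memberships.to_numpy(dtype=float)
    y = data.outcome.to_numpy(dtype=float)
    ambiguous = (m == 0.5).any(axis=1)
    n_excluded = int(ambiguous.sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} case(s) with a membership exactly 0.5 excluded "
            "from truth-table assignment",
            stacklevel=2,
        )
    bits = (m[~ambiguous] > 0.5).astype(int)
    y_kept = y[~ambiguous]
    crisp = data.crisp

    recs = []
    configs, inverse = np.unique(bits, axis=0, return_inverse=True)
    for k, cfg in enumerate(configs):
        in_row = inverse == k
        n_row = int(in_row.sum())
        x_cfg = _config_membership(data, cfg)
        cons = sufficiency(x_cfg, y).consistency
        contradictory = bool(crisp and len(set(y_kept[in_row])) > 1)
        recs.append(
            dict(
                zip(data.conditions, (int(v) for v in cfg)),
                n=n_row,
                consistency=cons,
                outcome=int(cons >= cons_cutoff),
                contradictory=contradictory,
                remainder=bool(n_row < freq_cutoff),
            )
        )
    rows = pd.DataFrame.from_records(recs).sort_values(
        data.conditions, ascending=False, ignore_index=True
    )
    return TruthTable(
        rows=rows,
        conditions=data.conditions,
        dataset=data,
        freq_cutoff=freq_cutoff,
        cons_cutoff=cons_cutoff,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# minimization (Quine-McCluskey, conservative solution)
# ---------------------------------------------------------------------------

def _term_covers(term, minterm) -> bool:
    return all(t is None or t == b for t, b in zip(term, minterm))


def _term_label(term, conditions) -> str:
    lits = [
        name if bit == 1 else f"~{name}"
        for name, bit in zip(conditions, term)
        if bit is not None
    ]
    return "*".join(lits) if lits else "TRUE"


def _prime_implicants(on_set: set) -> set:
    """Prime implicants of the ON-set (no don't-cares): iterative pairwise
    reduction of terms over {0, 1, None}."""
    current = {tuple(m) for m in on_set}
    primes = set()
    while current:
        merged = set()
        next_terms = set()
        cur = sorted(current, key=_term_key)
        for t1, t2 in itertools.combinations(cur, 2):
            diff = [
                i
                for i, (a, b) in enumerate(zip(t1, t2))
                if a != b
            ]
            if len(diff) == 1 and t1[diff[0]] is not None and t2[diff[0]] is not None:
                new = list(t1)
                new[diff[0]] = None
                next_terms.add(tuple(new))
                merged.add(t1)
                merged.add(t2)
        primes |= current - merged
        current = next_terms
    return primes


def _irredundant_cover(primes: set, on_set: set) -> list:
    """Essential primes first, then greedy, then redundancy elimination."""
    cover_map = {p: {m for m in on_set if _term_covers(p, m)} for p in primes}
    chosen = []
    uncovered = set(on_set)
    # essential primes
    for m in sorted(on_set):
        covering = [p for p in primes if m in cover_map[p]]
        if len(covering) == 1 and covering[0] not in chosen:
            chosen.append(covering[0])
    for p in chosen:
        uncovered -= cover_map[p]
    while uncovered:
        best = max(
            sorted(primes - set(chosen), key=_term_key),
            key=lambda p: len(cover_map[p] & uncovered),
        )
        chosen.append(best)
        uncovered -= cover_map[best]
    # drop redundant terms (kept deterministic: revisit in sorted order)
    for p in sorted(chosen, key=_term_key):
        rest = [q for q in chosen if q != p]
        if rest and set().union(*(cover_map[q] for q in rest)) >= on_set:
            chosen = rest
    return chosen


@dataclass
class QCASolution:
    """Minimized sufficient configurations with set-theoretic fit measures."""

    terms: list[tuple]  # each over {0, 1, None}, one slot per condition
    conditions: list[str]
    consistency: float
    coverage: float
    term_measures: pd.DataFrame  # per-term consistency/coverage
    necessity_report: pd.DataFrame  # per-condition necessity consistency/coverage
    tautology: bool = False

    @property
    def expression(self) -> str:
        return " + ".join(_term_label(t, self.conditions) for t in self.terms)

    def __str__(self):
        return self.expression

    def membership(self, data: QCADataset) -> np.ndarray:
        """Fuzzy membership of the solution (max over terms) for each case."""
        if self.tautology:
            return np.ones(len(data.memberships))
        per_term = [
            _term_membership(t, data) for t in self.terms
        ]
        return np.max(per_term, axis=0)


def _term_membership(term, data: QCADataset) -> np.ndarray:
    m = data.memberships.to_numpy(dtype=float)
    vals = np.ones(len(m))
    for j, bit in enumerate(term):
        if bit is None:
            continue
        col = m[:, j] if bit == 1 else 1.0 - m[:, j]
        vals = np.minimum(vals, col)
    return vals


def minimize(table: TruthTable) -> QCASolution:
    """Conservative Quine-McCluskey minimization of the positive rows.

    Remainder rows are excluded from the ON-set and never used as
    counterfactuals; the solution is logically equivalent to the disjunction
    of the positively coded rows. Consistency and coverage are computed
    against the original case memberships.
    """
    rows = table.rows
    usable = rows[~rows["remainder"]]
    pos = usable[usable["outcome"] == 1]
    neg = usable[usable["outcome"] == 0]
    if len(pos) == 0:
        raise StructuralError("no positively coded truth-table rows to minimize")
    data = table.dataset
    y = data.outcome.to_numpy(dtype=float)

    k = len(table.conditions)
    tautology = len(neg) == 0 and len(pos) == 2**k
    if len(neg) == 0 and not tautology:
        # observed rows all positive, but not every configuration observed:
        # unobserved configurations still count as negative (conservative).
        pass
    if tautology:
        warnings.warn("every configuration is positive: solution is TRUE", stacklevel=2)
        nec_rep = _necessity_report(data)
        return QCASolution(
            terms=[tuple([None] * k)],
            conditions=table.conditions,
            consistency=sufficiency(np.ones(len(y)), y).consistency,
            coverage=sufficiency(np.ones(len(y)), y).coverage,
            term_measures=pd.DataFrame(
                {"term": ["TRUE"], "consistency": [np.nan], "coverage": [np.nan]}
            ),
            necessity_report=nec_rep,
            tautology=True,
        )

    on_set = {tuple(int(r[c]) for c in table.conditions) for _, r in pos.iterrows()}
    primes = _prime_implicants(on_set)
    # conservative: an implicant must not cover any configuration outside the ON-set
    primes = {
        p
        for p in primes
        if all(
            tuple(m) in on_set
            for m in itertools.product(*[(0, 1) if b is None else (b,) for b in p])
        )
    }
    chosen = _irredundant_cover(primes, on_set)
    chosen = sorted(
        chosen, key=lambda t: (sum(b is not None for b in t), _term_label(t, table.conditions))
    )

    sol_m = np.max([_term_membership(t, data) for t in chosen], axis=0)
    overall = sufficiency(sol_m, y)
    term_rows = []
    for t in chosen:
        tm = _term_membership(t, data)
        meas = sufficiency(tm, y)
        term_rows.append(
            {
                "term": _term_label(t, table.conditions),
                "consistency": meas.consistency,
                "coverage": meas.coverage,
            }
        )
    return QCASolution(
        terms=chosen,
        conditions=table.conditions,
        consistency=overall.consistency,
        coverage=overall.coverage,
        term_measures=pd.DataFrame(term_rows),
        necessity_report=_necessity_report(data),
    )


def _necessity_report(data: QCADataset) -> pd.DataFrame:
    y = data.outcome.to_numpy(dtype=float)
    rows = []
    for name in data.conditions:
        x = data.memberships[name].to_numpy(dtype=float)
        try:
            meas = necessity(x, y)
            rows.append(
                {"condition": name, "consistency": meas.consistency, "coverage": meas.coverage}
            )
        except UndefinedResultError:
            rows.append({"condition": name, "consistency": np.nan, "coverage": np.nan})
    return pd.DataFrame(rows)


def analyze_qca(
    data: QCADataset, freq_cutoff: int = 1, cons_cutoff: float = 0.8
) -> QCASolution:
    """Truth table construction followed by conservative minimization."""
    return minimize(build_truth_table(data, freq_cutoff=freq_cutoff, cons_cutoff=cons_cutoff))
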