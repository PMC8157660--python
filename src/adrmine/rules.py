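"""Sequential-covering (RIPPER-style) rule induction over binary features.

The learner produces an ordered list of rules of the form

    (f_1 AND f_2 AND ... ) AND (NOT g_1 AND NOT g_2 AND ...)  =>  POS

with a default NEG conclusion, where the target class is the minority
class.  Each rule is grown greedily on two thirds of the remaining
training data by adding the literal (a feature affirmed or negated)
maximizing FOIL information gain, then pruned on the remaining third by
maximizing (p - n) / (p + n).  Rules must cover at least ``min_cover``
training instances; covered examples are removed between rules.
Optimization passes re-grow each rule and keep whichever of the
original, replacement, or revision variant minimizes whole-train error
— a simplified stand-in for RIPPER's description-length bookkeeping
that preserves the rule form and stopping behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_MIN_COVER = 5
DEFAULT_OPTIMIZE_ROUNDS = 2

#: a literal is (feature index, affirmed flag)
Literal = tuple[int, bool]


@dataclass(frozen=True)
class Rule:
    literals: tuple[Literal, ...]
    pos_cover: int = 0
    neg_cover: int = 0

    @property
    def coverage(self) -> int:
        return self.pos_cover + self.neg_cover


@dataclass
class RuleModel:
    """Ordered positive-class rules with a default negative conclusion."""

    rules: list[Rule] = field(default_factory=list)
    n_features: int = 0
    target_is_pos: bool = True  # False when POS was not the minority class

    def features_used(self) -> set[int]:
        return {j for rule in self.rules for j, _ in rule.literals}

    def render(self, feature_names: Sequence[str] | None = None) -> str:
        name = (lambda j: feature_names[j]) if feature_names is not None else (lambda j: f"f{j}")
        target = "POS" if self.target_is_pos else "NEG"
        default = "NEG" if self.target_is_pos else "POS"
        lines = []
        for rule in self.rules:
            parts = [(name(j) if aff else f"NOT {name(j)}") for j, aff in rule.literals]
            lines.append(
                " AND ".join(parts)
                + f" => {target}  ({rule.pos_cover} pos / {rule.neg_cover} neg covered)"
            )
        lines.append(f"otherwise => {default}")
        return "\n".join(lines)

    def to_json_obj(self, feature_names: Sequence[str] | None = None) -> dict:
        name = (lambda j: feature_names[j]) if feature_names is not None else (lambda j: f"f{j}")
        return {
            "target": "POS" if self.target_is_pos else "NEG",
            "default": "NEG" if self.target_is_pos else "POS",
            "rules": [
                {
                    "literals": [
                        {"feature": name(j), "affirmed": bool(aff)} for j, aff in rule.literals
                    ],
                    "pos_cover": rule.pos_cover,
                    "neg_cover": rule.neg_cover,
                }
                for rule in self.rules
            ],
        }


def _covers(literals: tuple[Literal, ...], X: np.ndarray) -> np.ndarray:
    mask = np.ones(len(X), dtype=bool)
    for j, affirmed in literals:
        col = X[:, j].astype(bool)
        mask &= col if affirmed else ~col
    return mask


def _foil_gain(p0: int, n0: int, p1: int, n1: int) -> float:
    # Laplace-smoothed FOIL information gain of refining (p0, n0) -> (p1, n1)
    if p1 == 0:
        return -np.inf
    before = np.log2((p0 + 1) / (p0 + n0 + 2))
    after = np.log2((p1 + 1) / (p1 + n1 + 2))
    return p1 * (after - before)


def _grow_rule(X: np.ndarray, y: np.ndarray, forbidden: set[int] | None = None) -> tuple[Literal, ...]:
    """Greedily add the literal maximizing FOIL gain until no negative is
    covered or no literal improves."""
    literals: list[Literal] = []
    mask = np.ones(len(X), dtype=bool)
    used: set[int] = set(forbidden or ())
    while True:
        p0 = int((y & mask).sum())
        n0 = int((~y & mask).sum())
        if n0 == 0 or p0 == 0:
            break
        best, best_gain = None, 0.0
        for j in range(X.shape[1]):
            if j in used:
                continue
            col = X[:, j].astype(bool)
            for affirmed in (True, False):
                sub = mask & (col if affirmed else ~col)
                p1 = int((y & sub).sum())
                n1 = int((~y & sub).sum())
                gain = _foil_gain(p0, n0, p1, n1)
                if gain > best_gain + 1e-12:
                    best, best_gain = (j, affirmed), gain
        if best is None:
            break
        literals.append(best)
        used.add(best[0])
        col = X[:, best[0]].astype(bool)
        mask &= col if best[1] else ~col
    return tuple(literals)


def _prune_rule(literals: tuple[Literal, ...], X: np.ndarray, y: np.ndarray) -> tuple[Literal, ...]:
    """Keep the prefix of literals maximizing (p - n)/(p + n) on the prune
    set; ties prefer the shorter rule."""
    if not literals:
        return literals
    best_i, best_v = len(literals), -np.inf
    for i in range(1, len(literals) + 1):
        mask = _covers(literals[:i], X)
        p = int((y & mask).sum())
        n = int((~y & mask).sum())
        v = -np.inf if p + n == 0 else (p - n) / (p + n)
        if v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and i < best_i):
            best_i, best_v = i, v
    return literals[:best_i]


def _stratified_split(idx: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    grow, prune = [], []
    for cls in (True, False):
        members = idx[y[idx] == cls]
        members = members[rng.permutation(len(members))]
        cut = int(round(len(members) * 2 / 3))
        grow.extend(members[:cut])
        prune.extend(members[cut:])
    return np.array(sorted(grow), dtype=int), np.array(sorted(prune), dtype=int)


def _rule_stats(literals: tuple[Literal, ...], X: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    mask = _covers(literals, X)
    return int((y & mask).sum()), int((~y & mask).sum())


def _model_errors(rules: list[tuple[Literal, ...]], X: np.ndarray, y: np.ndarray) -> int:
    pred = np.zeros(len(X), dtype=bool)
    for lits in rules:
        pred |= _covers(lits, X)
    return int((pred != y).sum())


def induce_rules(
    X: np.ndarray,
    y: np.ndarray,
    min_cover: int = DEFAULT_MIN_COVER,
    optimize_rounds: int = DEFAULT_OPTIMIZE_ROUNDS,
    seed: int = 0,
) -> RuleModel:
    """Induce an ordered positive-class rule list by sequential covering.

    ``y`` holds booleans (True = POS).  POS must be the minority class;
    if it is not, the learner targets the actual minority class with a
    warning and records the swap on the model.  Rules failing the
    ``min_cover`` threshold or covering more negatives than positives on
    their prune set are rejected, which ends the covering loop.
    """
    X = np.asarray(X).astype(bool)
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    target_is_pos = True
    if n_pos > n_neg:
        warnings.warn("POS is not the minority class; learning rules for NEG instead")
        y = ~y
        target_is_pos = False
    rng = np.random.default_rng(seed)

    rule_literals: list[tuple[Literal, ...]] = []
    remaining = np.arange(len(y))
    while int(y[remaining].sum()) >= min_cover:
        grow_idx, prune_idx = _stratified_split(remaining, y, rng)
        lits = _grow_rule(X[grow_idx], y[grow_idx])
        if not lits:
            break
        if len(prune_idx):
            lits = _prune_rule(lits, X[prune_idx], y[prune_idx])
            p, n = _rule_stats(lits, X[prune_idx], y[prune_idx])
            if p + n > 0 and (p - n) / (p + n) < 0:
                break  # worse than chance on the prune set: stop covering
        p_full, n_full = _rule_stats(lits, X, y)
        if p_full + n_full < min_cover:
            break
        covered = _covers(lits, X)
        if not covered[remaining].any():
            break  # rule adds nothing on the remaining examples
        rule_literals.append(lits)
        remaining = remaining[~covered[remaining]]
        if not len(remaining):
            break

    for _ in range(max(0, optimize_rounds)):
        for i in range(len(rule_literals)):
            others = rule_literals[:i] + rule_literals[i + 1 :]
            other_cover = np.zeros(len(y), dtype=bool)
            for lits in others:
                other_cover |= _covers(lits, X)
            idx = np.nonzero(~other_cover)[0]
            if not len(idx) or int(y[idx].sum()) == 0:
                continue
            grow_idx, prune_idx = _stratified_split(idx, y, rng)
            replacement = _grow_rule(X[grow_idx], y[grow_idx])
            if len(prune_idx) and replacement:
                replacement = _prune_rule(replacement, X[prune_idx], y[prune_idx])
            candidates = [rule_literals[i]]
            if replacement:
                candidates.append(replacement)
            revision = rule_literals[i] + _grow_rule(
                X[grow_idx], y[grow_idx], forbidden={j for j, _ in rule_literals[i]}
            )
            if revision != rule_literals[i]:
                candidates.append(revision)
            candidates = [
                c for c in candidates if sum(_rule_stats(c, X, y)) >= min_cover
            ] or [rule_literals[i]]
            errors = [
                _model_errors(rule_literals[:i] + [c] + rule_literals[i + 1 :], X, y)
                for c in candidates
            ]
            rule_literals[i] = candidates[int(np.argmin(errors))]

    rules = []
    for lits in rule_literals:
        p, n = _rule_stats(lits, X, y)
        if p + n >= min_cover:
            rules.append(Rule(literals=lits, pos_cover=p, neg_cover=n))
    return RuleModel(rules=rules, n_features=X.shape[1], target_is_pos=target_is_pos)


def apply_rules(model: RuleModel, instance: Sequence[int]) -> str:
    """First matching rule fires; otherwise the default conclusion."""
    x = np.asarray(instance, dtype=bool).reshape(1, -1)
    target = "POS" if model.target_is_pos else "NEG"
    default = "NEG" if model.target_is_pos else "POS"
    for rule in model.rules:
        if _covers(rule.literals, x)[0]:
            return target
    return default


def predict(model: RuleModel, X: np.ndarray) -> np.ndarray:
    """Boolean POS predictions for a matrix of instances."""
    X = np.asarray(X).astype(bool)
    fired = np.zeros(len(X), dtype=bool)
    for rule in model.rules:
        fired |= _covers(rule.literals, X)
    return fired if model.target_is_pos else ~fired


class RuleModelAdapter:
    """Adapter giving a RuleModel the scoring surface cross_validate needs."""

    def __init__(self, model: RuleModel):
        self.model = model

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return predict(self.model, X).astype(float)


def rule_model_factory(min_cover: int = DEFAULT_MIN_COVER, optimize_rounds: int = DEFAULT_OPTIMIZE_ROUNDS):
    def factory(X, y, seed):
        return RuleModelAdapter(
            induce_rules(X, y, min_cover=min_cover, optimize_rounds=optimize_rounds, seed=seed)
        )

    return factory
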