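"""Multinomial processing tree structures and the EQN model-file format.

An MPT model maps a vector of process probabilities ``theta`` (one entry per
cognitive process parameter) onto the category probabilities of a product
multinomial experiment.  Each *category system* (a "tree" in EQN parlance) is
one multinomial block; each category is reached by one or more *branches*, and
a branch probability is a product of parameters and complements,

    P(B_kji | theta) = prod_s theta_s**a[s] * (1 - theta_s)**b[s],

with non-negative integer exponents ``a``/``b`` counting how often the
parameter and its complement occur on the branch.  Category probabilities are
branch sums, and within a system they form a simplex.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CategorySystem",
    "MptModel",
    "Restriction",
    "parse_eqn",
    "parse_restriction",
    "apply_restrictions",
]

_FACTOR_RE = re.compile(r"^(?:\(\s*1\s*-\s*([A-Za-z_][\w.]*)\s*\)|([A-Za-z_][\w.]*))$")
_NUMBER_RE = re.compile(r"^\d+\s*$")


class EqnParseError(ValueError):
    """Raised when an EQN model description cannot be parsed."""


@dataclass
class CategorySystem:
    """One multinomial block: a labelled tree with its ordered categories."""

    label: str
    categories: list[str]
    #: per category, the list of *global* branch indices terminating in it
    branches_per_category: list[list[int]]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"duplicate category labels in system {self.label!r}")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass
class MptModel:
    """An MPT model: parameters, category systems, and branch exponents.

    Branches are indexed globally (rows of ``a_exponents``/``b_exponents``);
    each :class:`CategorySystem` records which branches terminate in each of
    its categories.  ``branch_constants`` carries multiplicative constants
    introduced by fixed-value parameter restrictions (1.0 for a plain model).
    """

    parameter_names: list[str]
    systems: list[CategorySystem]
    a_exponents: np.ndarray  # (n_branches, S) int
    b_exponents: np.ndarray  # (n_branches, S) int
    branch_constants: np.ndarray | None = None  # (n_branches,) float

    def __post_init__(self) -> None:
        self.a_exponents = np.asarray(self.a_exponents, dtype=np.int64)
        self.b_exponents = np.asarray(self.b_exponents, dtype=np.int64)
        if self.branch_constants is None:
            self.branch_constants = np.ones(self.a_exponents.shape[0])
        else:
            self.branch_constants = np.asarray(self.branch_constants, dtype=float)
        if np.any(self.a_exponents < 0) or np.any(self.b_exponents < 0):
            raise ValueError("branch exponents must be non-negative integers")
        if self.a_exponents.shape != self.b_exponents.shape:
            raise ValueError("exponent arrays must have identical shapes")
        if self.a_exponents.shape[1] != len(self.parameter_names):
            raise ValueError("exponent arrays inconsistent with parameter count")
        n_branches = self.a_exponents.shape[0]
        seen: set[int] = set()
        for sys_ in self.systems:
            for branches in sys_.branches_per_category:
                if not branches:
                    raise ValueError("every category needs at least one branch")
                for b in branches:
                    if not 0 <= b < n_branches:
                        raise ValueError(f"branch index {b} out of range")
                    seen.add(b)
        if len(seen) != n_branches:
            raise ValueError("unreferenced branches present")

    # -- basic dimensions ---------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def n_systems(self) -> int:
        return len(self.systems)

    @property
    def n_branches(self) -> int:
        return self.a_exponents.shape[0]

    @property
    def categories_per_system(self) -> list[int]:
        return [s.n_categories for s in self.systems]

    @property
    def n_categories_total(self) -> int:
        return sum(self.categories_per_system)

    @property
    def category_labels(self) -> list[str]:
        """Flat ``tree.category`` labels in model order."""
        return [f"{s.label}.{c}" for s in self.systems for c in s.categories]

    # -- flat index helpers used by the vectorized likelihood ---------------
    @property
    def branch_category_index(self) -> np.ndarray:
        """Flat category index of each global branch."""
        idx = np.empty(self.n_branches, dtype=np.int64)
        flat = 0
        for s in self.systems:
            for branches in s.branches_per_category:
                for b in branches:
                    idx[b] = flat
                flat += 1
        return idx

    @property
    def system_of_category(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_systems), self.categories_per_system)

    def parameter_index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    # -- probability evaluation ---------------------------------------------
    def _check_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[-1] != self.n_parameters:
            raise ValueError(
                f"theta must have length {self.n_parameters}, got {theta.shape[-1]}"
            )
        if np.any(theta <= 0.0) or np.any(theta >= 1.0):
            raise ValueError("theta must lie strictly inside the unit hypercube")
        return theta

    def _branch_logprobs(self, theta: np.ndarray) -> np.ndarray:
        """Log branch probabilities for one theta vector (log-space, safe
        for arbitrarily large exponents)."""
        with np.errstate(divide="ignore"):
            logc = np.log(self.branch_constants)
        return (
            self.a_exponents @ np.log(theta)
            + self.b_exponents @ np.log1p(-theta)
            + logc
        )

    def branch_probability(self, k: int, j: int, i: int, theta: np.ndarray) -> float:
        """P(B_kji | theta), the product over parameters on one branch."""
        theta = self._check_theta(theta)
        branch = self.systems[k].branches_per_category[j][i]
        return float(np.exp(self._branch_logprobs(theta)[branch]))

    def category_probability(self, k: int, j: int, theta: np.ndarray) -> float:
        """P(C_kj | theta), the sum of its branch probabilities."""
        theta = self._check_theta(theta)
        branches = self.systems[k].branches_per_category[j]
        return float(np.exp(self._branch_logprobs(theta)[branches]).sum())

    def category_probabilities(self, theta: np.ndarray) -> np.ndarray:
        """All category probabilities, flat in model order."""
        theta = self._check_theta(theta)
        pb = np.exp(self._branch_logprobs(theta))
        out = np.zeros(self.n_categories_total)
        np.add.at(out, self.branch_category_index, pb)
        return out

    # -- serialization -------------------------------------------------------
    def _branch_term(self, branch: int) -> str:
        factors: list[str] = []
        const = self.branch_constants[branch]
        if const != 1.0:
            factors.append(repr(float(const)))
        for s, name in enumerate(self.parameter_names):
            factors.extend([name] * int(self.a_exponents[branch, s]))
            factors.extend([f"(1-{name})"] * int(self.b_exponents[branch, s]))
        return "*".join(factors) if factors else "1"

    def to_eqn(self) -> str:
        """Serialize back to EQN text (headerless dialect)."""
        lines = []
        for sys_ in self.systems:
            for cat, branches in zip(sys_.categories, sys_.branches_per_category):
                for b in branches:
                    lines.append(f"{sys_.label} {cat} {self._branch_term(b)}")
        return "\n".join(lines) + "\n"

    def describe(self) -> str:
        """Human-readable table of trees, categories and branch terms."""
        rows = [f"MPT model: S={self.n_parameters} parameters "
                f"({', '.join(self.parameter_names)}), K={self.n_systems} systems"]
        for sys_ in self.systems:
            rows.append(f"tree {sys_.label}:")
            for cat, branches in zip(sys_.categories, sys_.branches_per_category):
                terms = " + ".join(self._branch_term(b) for b in branches)
                rows.append(f"  {cat}: {terms}")
        return "\n".join(rows)


@dataclass(frozen=True)
class Restriction:
    """A parameter restriction: equality (``u = a``) or fixation (``a = 0.5``)."""

    kind: str  # "equality" | "fixed-value"
    subject: str
    target: str | float

    def __post_init__(self) -> None:
        if self.kind not in ("equality", "fixed-value"):
            raise ValueError(f"unknown restriction kind {self.kind!r}")
        if self.kind == "fixed-value":
            v = float(self.target)
            if not 0.0 <= v <= 1.0:
                raise ValueError("fixed-value constants must lie in [0, 1]")


def parse_restriction(text: str) -> Restriction:
    """Parse ``"u=a"`` or ``"a=0.5"`` into a :class:`Restriction`."""
    lhs, sep, rhs = text.partition("=")
    if not sep:
        raise ValueError(f"restriction {text!r} must contain '='")
    lhs, rhs = lhs.strip(), rhs.strip()
    try:
        return Restriction("fixed-value", lhs, float(rhs))
    except ValueError:
        return Restriction("equality", lhs, rhs)


def _parse_term(term: str, lineno: int) -> list[tuple[str, bool]]:
    """Split a branch term into (parameter, is_complement) factors."""
    # normalize: allow whitespace around '*' and inside '(1 - x)'
    factors = []
    depth_safe = term.replace(" ", "")
    if not depth_safe:
        raise EqnParseError(f"line {lineno}: empty branch term")
    for raw in depth_safe.split("*"):
        m = _FACTOR_RE.match(raw)
        if m is None:
            raise EqnParseError(f"line {lineno}: malformed factor {raw!r}")
        if m.group(1) is not None:
            factors.append((m.group(1), True))
        else:
            factors.append((m.group(2), False))
    return factors


def parse_eqn(text: str) -> MptModel:
    """Parse an EQN-format model description into an :class:`MptModel`.

    Each content line reads ``tree category term`` where *term* is a product
    of parameter names and ``(1-name)`` factors joined by ``*``.  Both the
    "count-first-line" and headerless EQN dialects are accepted; blank lines
    and lines starting with ``#`` are ignored.  Lines sharing a
    (tree, category) pair contribute branches to the same category.
    """
    raw_lines = text.splitlines()
    content: list[tuple[int, str]] = []
    for lineno, line in enumerate(raw_lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#") or stripped.startswith("//"):
            continue
        content.append((lineno, stripped))
    if content and _NUMBER_RE.match(content[0][1]):
        content = content[1:]  # tolerated leading line-count header
    if not content:
        raise EqnParseError("no branch lines found")

    parameter_names: list[str] = []
    tree_order: list[str] = []
    # tree -> category -> list of branch factor-lists
    trees: dict[str, dict[str, list[list[tuple[str, bool]]]]] = {}
    for lineno, line in content:
        parts = line.split(None, 2)
        if len(parts) != 3:
            raise EqnParseError(
                f"line {lineno}: expected 'tree category term', got {line!r}"
            )
        tree, cat, term = parts
        factors = _parse_term(term, lineno)
        for name, _ in factors:
            if name not in parameter_names:
                parameter_names.append(name)
        if tree not in trees:
            trees[tree] = {}
            tree_order.append(tree)
        trees[tree].setdefault(cat, []).append(factors)

    S = len(parameter_names)
    if S == 0:
        raise EqnParseError("model declares no parameters")
    pindex = {name: s for s, name in enumerate(parameter_names)}

    a_rows: list[np.ndarray] = []
    b_rows: list[np.ndarray] = []
    systems: list[CategorySystem] = []
    for tree in tree_order:
        cats = list(trees[tree].keys())  # first-appearance order (py3.7+ dict)
        branch_lists: list[list[int]] = []
        for cat in cats:
            idxs: list[int] = []
            for factors in trees[tree][cat]:
                a = np.zeros(S, dtype=np.int64)
                b = np.zeros(S, dtype=np.int64)
                for name, is_comp in factors:
                    if is_comp:
                        b[pindex[name]] += 1
                    else:
                        a[pindex[name]] += 1
                idxs.append(len(a_rows))
                a_rows.append(a)
                b_rows.append(b)
            branch_lists.append(idxs)
        systems.append(CategorySystem(tree, cats, branch_lists))

    return MptModel(parameter_names, systems, np.array(a_rows), np.array(b_rows))


def apply_restrictions(model: MptModel, restrictions: list[Restriction]) -> MptModel:
    """Return a new model with parameter restrictions applied.

    Equality restrictions merge the subject's exponent counts onto the target
    parameter (reducing S); fixed-value restrictions remove the parameter and
    fold the constant into the branch constants.
    """
    if not restrictions:
        return model

    # resolve equality chains subject -> final target; detect cycles
    eq_map = {r.subject: r.target for r in restrictions if r.kind == "equality"}
    for r in restrictions:
        if r.subject not in model.parameter_names:
            raise KeyError(f"restriction references unknown parameter {r.subject!r}")
        if r.kind == "equality" and r.target not in model.parameter_names:
            raise KeyError(f"restriction references unknown parameter {r.target!r}")

    def resolve(name: str) -> str:
        seen = {name}
        while name in eq_map:
            name = eq_map[name]  # type: ignore[assignment]
            if name in seen:
                raise ValueError("cyclic equality restriction chain")
            seen.add(name)
        return name

    fixed = {r.subject: float(r.target) for r in restrictions if r.kind == "fixed-value"}
    removed = set(eq_map) | set(fixed)
    kept = [p for p in model.parameter_names if p not in removed]
    if not kept:
        raise ValueError("restrictions remove every parameter")
    new_index = {p: i for i, p in enumerate(kept)}

    nb = model.n_branches
    a_new = np.zeros((nb, len(kept)), dtype=np.int64)
    b_new = np.zeros((nb, len(kept)), dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_const = np.log(model.branch_constants.astype(float))

        def fold(lc, a_col, b_col, v):
            # 0 * log(0) must contribute nothing (exponent zero = factor absent)
            lc = lc + np.where(a_col > 0, a_col * np.log(v), 0.0)
            return lc + np.where(b_col > 0, b_col * np.log1p(-v), 0.0)

        for s, name in enumerate(model.parameter_names):
            a_col = model.a_exponents[:, s]
            b_col = model.b_exponents[:, s]
            if name in fixed:
                log_const = fold(log_const, a_col, b_col, fixed[name])
            else:
                tgt = resolve(name)
                if tgt in fixed:
                    log_const = fold(log_const, a_col, b_col, fixed[tgt])
                else:
                    t = new_index[tgt]
                    a_new[:, t] += a_col
                    b_new[:, t] += b_col
    const = np.exp(log_const)
    const[np.isneginf(log_const)] = 0.0

    systems = [
        CategorySystem(s.label, list(s.categories), [list(b) for b in s.branches_per_category])
        for s in model.systems
    ]
    return MptModel(kept, systems, a_new, b_new, const)
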