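"""Exact machinery for finite joint distributions p(X1, ..., Xn, Y).

Everything here is plug-in computation on explicit probability tables: marginal
entropies, (conditional) mutual information, the Gacs-Korner common random
variable obtained from connected components of the support graph, and the
redundancy oracle I_wedge(Y; X1, ..., Xn) = I(Y; Q) where Q is that common
variable.  These quantities are exact (up to float rounding) and serve as
ground truth for the neural estimator.

Canonical two-source benchmark distributions from the partial-information-
decomposition literature are built in (``make_canonical``): UNQ, AND, RDNXOR
and IMPERFECTRDN.

All information quantities are reported in bits (log base 2).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset

__all__ = [
    "JointPMF",
    "CommonVariable",
    "entropy_bits",
    "mutual_information_bits",
    "conditional_mi_bits",
    "gacs_korner_common",
    "i_cap_wedge_bits",
    "make_canonical",
    "sample_dataset",
    "CANONICAL_TASKS",
]

_MASS_TOL = 1e-12

Symbol = object  # hashable: int, str or tuple thereof
Key = tuple


def _as_tuple(x) -> tuple:
    return tuple(x) if isinstance(x, (tuple, list)) else (x,)


@dataclass(frozen=True)
class JointPMF:
    """Explicit probability table over ``(X1, ..., Xn, Y)``.

    Parameters
    ----------
    source_alphabets
        One finite symbol set per source.  Symbols may be scalars or tuples
        (a tuple symbol expands to one feature column per element when the
        distribution is sampled into a dataset).
    target_alphabet
        Finite symbol set of the target ``Y``.
    table
        Map from ``(x1, ..., xn, y)`` to probability mass.  Masses must be
        non-negative and sum to one within 1e-12; zero-mass keys are allowed
        and excluded from the support.
    """

    source_alphabets: tuple[tuple, ...]
    target_alphabet: tuple
    table: Mapping[Key, float]

    def __post_init__(self):
        object.__setattr__(
            self,
            "source_alphabets",
            tuple(tuple(a) for a in self.source_alphabets),
        )
        object.__setattr__(self, "target_alphabet", tuple(self.target_alphabet))
        object.__setattr__(self, "table", dict(self.table))
        if not self.source_alphabets:
            raise ValueError("at least one source alphabet is required")
        total = 0.0
        support = 0
        for key, p in self.table.items():
            if len(key) != self.n_sources + 1:
                raise ValueError(f"key {key!r} has wrong arity for {self.n_sources} sources")
            for i, sym in enumerate(key[:-1]):
                if sym not in self.source_alphabets[i]:
                    raise ValueError(f"symbol {sym!r} not in alphabet of source {i}")
            if key[-1] not in self.target_alphabet:
                raise ValueError(f"target symbol {key[-1]!r} not in target alphabet")
            if p < 0:
                raise ValueError(f"negative mass {p} at {key!r}")
            if p > 0:
                support += 1
            total += p
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"masses sum to {total!r}, not 1")
        if support == 0:
            raise ValueError("support is empty")

    # ------------------------------------------------------------ structure
    @property
    def n_sources(self) -> int:
        return len(self.source_alphabets)

    @property
    def variables(self) -> tuple[str, ...]:
        """Variable names: ``x1, ..., xn, y``."""
        return tuple(f"x{i + 1}" for i in range(self.n_sources)) + ("y",)

    def support(self) -> list[Key]:
        """Keys with strictly positive mass."""
        return [k for k, p in self.table.items() if p > 0]

    def _var_index(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise ValueError(f"unknown variable {name!r}; choose from {self.variables}")

    def marginal(self, which: Iterable[str] | str) -> dict[tuple, float]:
        """Marginal table over the named variables (values keyed in given order)."""
        names = [which] if isinstance(which, str) else list(which)
        if not names:
            raise ValueError("variable subset must be non-empty")
        idx = [self._var_index(n) for n in names]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate variables in {names}")
        out: dict[tuple, float] = {}
        for key, p in self.table.items():
            if p <= 0:
                continue
            sub = tuple(key[i] for i in idx)
            out[sub] = out.get(sub, 0.0) + p
        return out

    def drop_sources(self, keep: Sequence[int]) -> "JointPMF":
        """Marginal joint pmf over a subset of sources (plus the target)."""
        keep = list(keep)
        if not keep:
            raise ValueError("must keep at least one source")
        table: dict[Key, float] = {}
        for key, p in self.table.items():
            if p <= 0:
                continue
            sub = tuple(key[i] for i in keep) + (key[-1],)
            table[sub] = table.get(sub, 0.0) + p
        return JointPMF(
            tuple(self.source_alphabets[i] for i in keep), self.target_alphabet, table
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the table with columns ``x1, ..., xn, y, p`` (symbols as strings)."""
        rows = [
            {**{f"x{i + 1}": repr(key[i]) for i in range(self.n_sources)},
             "y": repr(key[-1]), "p": p}
            for key, p in self.table.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "JointPMF":
        """Read a table written by :meth:`to_csv`."""
        df = pd.read_csv(path)
        xcols = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not xcols or "y" not in df.columns or "p" not in df.columns:
            raise ValueError(f"{path}: expected columns x1..xn, y, p")

        def parse(v):
            try:
                return ast.literal_eval(str(v))
            except (ValueError, SyntaxError):
                return str(v)

        table: dict[Key, float] = {}
        alphabets: list[set] = [set() for _ in xcols]
        targets: set = set()
        for _, row in df.iterrows():
            key = tuple(parse(row[c]) for c in xcols) + (parse(row["y"]),)
            for i, sym in enumerate(key[:-1]):
                alphabets[i].add(sym)
            targets.add(key[-1])
            table[key] = table.get(key, 0.0) + float(row["p"])
        return cls(
            tuple(tuple(sorted(a, key=repr)) for a in alphabets),
            tuple(sorted(targets, key=repr)),
            table,
        )


@dataclass(frozen=True)
class CommonVariable:
    """A random variable expressible as a deterministic function of every source.

    ``labeling[i]`` maps each supported symbol of source ``i`` to a block
    identifier in ``range(n_blocks)``; on every support point all sources'
    symbols map to the same block, which is what makes the block label a
    common random variable.
    """

    labeling: tuple[Mapping[Symbol, int], ...]
    n_blocks: int

    def __post_init__(self):
        object.__setattr__(self, "labeling", tuple(dict(m) for m in self.labeling))
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        for m in self.labeling:
            for b in m.values():
                if not 0 <= b < self.n_blocks:
                    raise ValueError(f"block {b} out of range [0, {self.n_blocks})")

    def block_of(self, key: Key) -> int:
        """Block of a support point; raises if the sources disagree."""
        blocks = {self.labeling[i][sym] for i, sym in enumerate(key[:-1])}
        if len(blocks) != 1:
            raise ValueError(f"sources disagree on the block of {key!r}")
        return blocks.pop()


# ---------------------------------------------------------------------------
# plug-in information quantities
# ---------------------------------------------------------------------------

def _entropy_from_masses(masses: Iterable[float]) -> float:
    p = np.asarray([m for m in masses if m > 0])
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _check_disjoint(*subsets: Sequence[str]) -> None:
    seen: set[str] = set()
    for sub in subsets:
        s = set(sub)
        if not s:
            raise ValueError("variable subsets must be non-empty")
        if seen & s:
            raise ValueError(f"variable subsets overlap on {sorted(seen & s)}")
        seen |= s


def _names(which: Iterable[str] | str) -> list[str]:
    return [which] if isinstance(which, str) else list(which)


def entropy_bits(pmf: JointPMF, which: Iterable[str] | str) -> float:
    """Plug-in Shannon entropy of the marginal over ``which``, in bits."""
    return _entropy_from_masses(pmf.marginal(which).values())


def mutual_information_bits(
    pmf: JointPMF, a: Iterable[str] | str, b: Iterable[str] | str
) -> float:
    """I(A; B) = H(A) + H(B) - H(A, B), in bits (non-negative up to rounding)."""
    a, b = _names(a), _names(b)
    _check_disjoint(a, b)
    return entropy_bits(pmf, a) + entropy_bits(pmf, b) - entropy_bits(pmf, a + b)


def conditional_mi_bits(
    pmf: JointPMF,
    a: Iterable[str] | str,
    b: Iterable[str] | str,
    c: Iterable[str] | str,
) -> float:
    """I(A; B | C) = H(A,C) + H(B,C) - H(A,B,C) - H(C), in bits."""
    a, b, c = _names(a), _names(b), _names(c)
    _check_disjoint(a, b, c)
    return (
        entropy_bits(pmf, a + c)
        + entropy_bits(pmf, b + c)
        - entropy_bits(pmf, a + b + c)
        - entropy_bits(pmf, c)
    )


# ---------------------------------------------------------------------------
# Gacs-Korner common variable and the wedge redundancy oracle
# ---------------------------------------------------------------------------

def gacs_korner_common(pmf: JointPMF) -> CommonVariable:
    """Finest common random variable of the sources.

    Builds the n-partite graph whose vertices are the supported source symbols
    and whose edges join symbols co-occurring in a support point; connected
    components give the block labels.  Any random variable that is a
    deterministic function of every source is a coarsening of this labeling.
    """
    if pmf.n_sources < 2:
        raise ValueError(
            "common variable needs >= 2 sources; "
            "self-redundancy of one source is its mutual information with y"
        )
    # union-find over (source index, symbol) vertices
    parent: dict[tuple[int, Symbol], tuple[int, Symbol]] = {}

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:  # path compression
            parent[v], v = root, parent[v]
        return root

    def union(u, v):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    for key in pmf.support():
        verts = [(i, sym) for i, sym in enumerate(key[:-1])]
        for v in verts:
            parent.setdefault(v, v)
        for v in verts[1:]:
            union(verts[0], v)

    roots: dict[tuple[int, Symbol], int] = {}
    labeling: list[dict[Symbol, int]] = [dict() for _ in range(pmf.n_sources)]
    for (i, sym) in parent:
        r = find((i, sym))
        block = roots.setdefault(r, len(roots))
        labeling[i][sym] = block
    return CommonVariable(tuple(labeling), n_blocks=len(roots))


def i_cap_wedge_bits(pmf: JointPMF) -> float:
    """Redundancy I(Y; Q) of the Gacs-Korner common variable Q, in bits.

    This equals the maximum of I(Y; Q) over all Q that are deterministic
    functions of every source: any admissible Q is a function of the finest
    common variable, so by data processing none can carry more information.
    """
    common = gacs_korner_common(pmf)
    joint: dict[tuple, float] = {}
    for key, p in pmf.table.items():
        if p <= 0:
            continue
        qy = (common.block_of(key), key[-1])
        joint[qy] = joint.get(qy, 0.0) + p
    h_q = _entropy_from_masses(
        _sum_over(joint, 0).values()
    )
    h_y = _entropy_from_masses(_sum_over(joint, 1).values())
    h_qy = _entropy_from_masses(joint.values())
    return h_q + h_y - h_qy


def _sum_over(joint: Mapping[tuple, float], keep: int) -> dict:
    out: dict = {}
    for key, p in joint.items():
        out[key[keep]] = out.get(key[keep], 0.0) + p
    return out


# ---------------------------------------------------------------------------
# canonical two-source benchmark distributions
# ---------------------------------------------------------------------------

CANONICAL_TASKS = ("UNQ", "AND", "RDNXOR", "IMPERFECTRDN")


def make_canonical(task: str) -> JointPMF:
    """Canonical PID benchmark distributions.

    - ``UNQ``: a, b iid uniform bits; X1 = a, X2 = b, Y = (a, b).  Each source
      carries 1 bit of unique information and there is no redundancy.
    - ``AND``: X1, X2 iid uniform bits, Y = X1 AND X2.  Redundancy lies in
      [0, 0.311] depending on the measure; deterministic-decoder measures
      give 0.
    - ``RDNXOR``: a, b, c iid uniform bits; X1 = (a, c), X2 = (b, c),
      Y = (a XOR b, c).  One redundant bit (the shared c) and one synergistic
      bit (the XOR).
    - ``IMPERFECTRDN``: P(0,0,0) = 0.499, P(0,1,0) = 0.001, P(1,1,1) = 0.5.
      X1 copies Y; X2 is an almost-perfect copy, giving 0.99 bits of
      (non-deterministic) redundancy while the common-variable oracle gives 0.
    """
    name = task.upper()
    if name == "UNQ":
        bits = (0, 1)
        table = {
            (a, b, (a, b)): 0.25 for a in bits for b in bits
        }
        return JointPMF(
            (bits, bits),
            tuple((a, b) for a in bits for b in bits),
            table,
        )
    if name == "AND":
        bits = (0, 1)
        table = {(a, b, a & b): 0.25 for a in bits for b in bits}
        return JointPMF((bits, bits), bits, table)
    if name == "RDNXOR":
        bits = (0, 1)
        pairs = tuple((u, v) for u in bits for v in bits)
        table: dict[Key, float] = {}
        for a in bits:
            for b in bits:
                for c in bits:
                    key = ((a, c), (b, c), (a ^ b, c))
                    table[key] = table.get(key, 0.0) + 0.125
        return JointPMF((pairs, pairs), pairs, table)
    if name == "IMPERFECTRDN":
        bits = (0, 1)
        table = {(0, 0, 0): 0.499, (0, 1, 0): 0.001, (1, 1, 1): 0.5}
        return JointPMF((bits, bits), bits, table)
    raise ValueError(f"unknown canonical task {task!r}; choose from {CANONICAL_TASKS}")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _symbol_width(alphabet: Sequence[Symbol]) -> int:
    widths = {len(_as_tuple(s)) for s in alphabet}
    if len(widths) != 1:
        raise ValueError("all symbols of a source must encode to the same width")
    return widths.pop()


def sample_dataset(pmf: JointPMF, n: int, seed: int) -> LabeledDataset:
    """Draw ``n`` iid observations from the joint table.

    Source symbols become numeric feature vectors (tuple symbols expand to one
    column per element, in tuple order); the target symbol becomes its index
    in ``target_alphabet``.  Identical seeds give bitwise-identical datasets.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    keys = pmf.support()
    masses = np.array([pmf.table[k] for k in keys])
    masses = masses / masses.sum()
    draws = rng.choice(len(keys), size=n, p=masses)

    widths = [_symbol_width(a) for a in pmf.source_alphabets]
    sources = [np.empty((n, w), dtype=np.float64) for w in widths]
    labels = np.empty(n, dtype=np.int64)
    target_index = {sym: j for j, sym in enumerate(pmf.target_alphabet)}
    for row, ki in enumerate(draws):
        key = keys[ki]
        for i in range(pmf.n_sources):
            sources[i][row] = _as_tuple(key[i])
        labels[row] = target_index[key[-1]]
    return LabeledDataset(sources, labels, n_classes=len(pmf.target_alphabet))
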