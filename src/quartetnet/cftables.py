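"""Observed quartet concordance factors.

A quartet CF table summarizes a multi-locus data set: for each sampled
4-taxon set, the number of genes whose (unrooted) gene tree displays each of
the three quartet splits, in the canonical order q1 = t1t2|t3t4,
q2 = t1t3|t2t4, q3 = t1t4|t2t3 for sorted taxa t1 < t2 < t3 < t4.  Genes
missing any of the four taxa, or unresolved on them, simply do not count for
that set.  Tables round-trip through a CSV dialect compatible with the
TICR/BUCKy pipeline (columns taxon1..taxon4, CF12_34, CF13_24, CF14_23,
optional *_lo/*_hi 95% credibility bounds and ngenes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneTree",
    "GeneTreeSample",
    "QuartetCFRecord",
    "QuartetCFTable",
    "quartet_sets",
    "quartet_coverage",
    "count_quartets",
    "read_cf_table",
    "write_cf_table",
    "read_gene_trees",
    "concordance_prior",
    "resample_cf_table",
]

CF_ROW_TOL = 1e-6


# ---------------------------------------------------------------------------
# light-weight gene trees (possibly multifurcating, possibly missing taxa)
# ---------------------------------------------------------------------------

@dataclass
class GClade:
    """One clade of a gene tree; leaves have a name and no children."""

    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: tuple = ()


class GeneTree:
    """A single gene tree, treated as unrooted for quartet extraction."""

    __slots__ = ("root", "_cache")

    def __init__(self, root: GClade):
        self.root = root
        self._cache = None

    def leaf_names(self) -> list[str]:
        out = []

        def walk(c: GClade):
            if not c.children:
                out.append(c.name)
            for ch in c.children:
                walk(ch)

        walk(self.root)
        return out

    def splits(self, index: dict[str, int]) -> tuple[int, list[tuple[int, Optional[float]]]]:
        """(present-taxon bitmask, [(clade bitmask, support), ...]).

        One entry per internal edge of the rooted representation; since the
        tree is read unrooted, each bitmask or its complement within the
        present mask encodes one bipartition.
        """
        if self._cache is not None:
            return self._cache
        edges: list[tuple[int, Optional[float]]] = []

        def walk(c: GClade) -> int:
            if not c.children:
                if c.name in index:
                    return 1 << index[c.name]
                raise KeyError(f"taxon {c.name!r} not in the sample's taxon set")
            m = 0
            for ch in c.children:
                sub = walk(ch)
                if ch.children:
                    edges.append((sub, ch.support))
                m |= sub
            return m

        present = walk(self.root)
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("gene tree has duplicate leaf labels")
        self._cache = (present, edges)
        return self._cache

    def to_newick(self, digits: int = 10) -> str:
        def fmt(x):
            return "" if x is None else f"{x:.{digits}g}"

        def render(c: GClade) -> str:
            if not c.children:
                base = c.name or ""
            else:
                base = "(" + ",".join(render(ch) for ch in c.children) + ")"
                if c.support is not None:
                    base += fmt(c.support)
            if c.length is not None:
                base += f":{fmt(c.length)}"
            return base

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "GeneTree":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("missing terminal ';'")

        stop = set("(),:;")

        def scan(i):
            j = i
            while j < len(text) and text[j] not in stop and not text[j].isspace():
                j += 1
            return text[i:j], j

        def subtree(i):
            name = None
            support = None
            children = []
            if text[i] == "(":
                i += 1
                while True:
                    child, i = branch(i)
                    children.append(child)
                    if text[i] == ",":
                        i += 1
                        continue
                    if text[i] == ")":
                        i += 1
                        break
                    raise ValueError(f"bad newick near position {i}")
                label, i = scan(i)
                if label:
                    try:
                        support = float(label)
                    except ValueError:
                        name = label  # named internal node
            else:
                label, i = scan(i)
                name = label or None
            return name, support, tuple(children), i

        def branch(i):
            name, support, children, i = subtree(i)
            length = None
            if i < len(text) and text[i] == ":":
                num, i = scan(i + 1)
                length = float(num) if num else None
            return GClade(name, length, support, children), i

        clade, i = branch(0)
        if i != len(text) - 1:
            raise ValueError(f"trailing characters at position {i}")
        return cls(clade)


@dataclass
class GeneTreeSample:
    """Gene trees over a common taxon set; trees may miss taxa."""

    taxa: list[str]
    trees: list[GeneTree]

    def __post_init__(self):
        self.taxa = sorted(self.taxa)

    @classmethod
    def from_trees(cls, trees: Iterable[GeneTree]) -> "GeneTreeSample":
        trees = list(trees)
        names: set[str] = set()
        for t in trees:
            names.update(t.leaf_names())
        return cls(sorted(names), trees)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick() + "\n")


def read_gene_trees(path) -> GeneTreeSample:
    """One Newick tree per line; internal node labels read as supports."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(GeneTree.from_newick(line))
    return GeneTreeSample.from_trees(trees)


# ---------------------------------------------------------------------------
# CF records and tables
# ---------------------------------------------------------------------------

@dataclass
class QuartetCFRecord:
    """Observed CFs for one 4-taxon set.

    ``cf`` holds the three normalized concordance factors; ``ngenes`` the
    effective number of informative genes, so the multinomial counts are
    approximately cf * ngenes.  ``lo``/``hi`` are optional per-split 95%
    credibility bounds.
    """

    taxa: tuple[str, str, str, str]
    cf: tuple[float, float, float]
    ngenes: Optional[float] = None
    lo: Optional[tuple[float, float, float]] = None
    hi: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        if list(self.taxa) != sorted(self.taxa):
            raise ValueError("record taxa must be sorted")
        s = sum(self.cf)
        if abs(s - 1.0) > CF_ROW_TOL:
            raise ValueError(f"CFs for {self.taxa} sum to {s}")
        if s != 1.0:
            self.cf = tuple(x / s for x in self.cf)
        if (self.lo is None) != (self.hi is None):
            raise ValueError("lo and hi bounds must be given together")
        if self.lo is not None:
            for c, a, b in zip(self.cf, self.lo, self.hi):
                if not (a - CF_ROW_TOL <= c <= b + CF_ROW_TOL):
                    raise ValueError(
                        f"CF {c} outside bounds [{a}, {b}] for {self.taxa}")

    def counts(self, fractional: bool = False) -> tuple[float, float, float]:
        if self.ngenes is None:
            raise ValueError(f"record {self.taxa} has no ngenes")
        x = tuple(c * self.ngenes for c in self.cf)
        return x if fractional else tuple(round(v) for v in x)


@dataclass
class QuartetCFTable:
    """All sampled 4-taxon sets of one analysis."""

    records: list[QuartetCFRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if r.taxa in seen:
                raise ValueError(f"duplicate 4-taxon set {r.taxa}")
            seen.add(r.taxa)

    @property
    def taxa(self) -> list[str]:
        out: set[str] = set()
        for r in self.records:
            out.update(r.taxa)
        return sorted(out)

    def has_bounds(self) -> bool:
        return bool(self.records) and all(r.lo is not None for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        with_bounds = any(r.lo is not None for r in self.records)
        for r in self.records:
            row = dict(zip(("taxon1", "taxon2", "taxon3", "taxon4"), r.taxa))
            for i, col in enumerate(("CF12_34", "CF13_24", "CF14_23")):
                row[col] = r.cf[i]
                if with_bounds and r.lo is not None:
                    row[col + "_lo"] = r.lo[i]
                    row[col + "_hi"] = r.hi[i]
            if r.ngenes is not None:
                row["ngenes"] = r.ngenes
            rows.append(row)
        return pd.DataFrame(rows)


def quartet_sets(taxa: Sequence[str], mode="all", seed: Optional[int] = None
                 ) -> list[tuple[str, str, str, str]]:
    """The 4-taxon sets to analyze.

    mode: "all" for all C(n,4) sets in canonical order; an integer m for a
    reproducible random subsample of m distinct sets; or an explicit list of
    4-taxon sets (each canonicalized by sorting).
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    if mode == "all":
        return list(itertools.combinations(taxa, 4))
    if isinstance(mode, int):
        total = math.comb(len(taxa), 4)
        if mode > total:
            raise ValueError(f"requested {mode} sets but only {total} exist")
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=mode, replace=False)
        idx.sort()
        allsets = list(itertools.combinations(taxa, 4))
        return [allsets[i] for i in idx]
    sets = [tuple(sorted(s)) for s in mode]
    if len(set(sets)) != len(sets):
        raise ValueError("duplicate 4-taxon sets requested")
    for s in sets:
        if len(set(s)) != 4 or not set(s) <= set(taxa):
            raise ValueError(f"bad 4-taxon set {s}")
    return sets


def quartet_coverage(sets: Iterable[Sequence[str]]) -> dict[str, int]:
    """How many sampled 4-taxon sets involve each taxon (flags
    under-represented taxa)."""
    cov: dict[str, int] = {}
    for s in sets:
        for t in s:
            cov[t] = cov.get(t, 0) + 1
    return cov


def count_quartets(sample: GeneTreeSample,
                   sets: Optional[Sequence[Sequence[str]]] = None,
                   support_threshold: Optional[float] = None
                   ) -> QuartetCFTable:
    """Count, per 4-taxon set, the genes displaying each quartet split.

    A gene counts for a set only if it carries all four taxa and its
    restriction to them is resolved.  With a support threshold, the gene
    additionally needs an internal edge inducing the displayed split with
    support >= threshold (absent support values pass).  Sets left with no
    informative gene are omitted.
    """
    if not sample.trees:
        raise ValueError("empty gene-tree sample")
    index = {t: i for i, t in enumerate(sample.taxa)}
    if sets is None:
        sets = quartet_sets(sample.taxa, "all")
    else:
        sets = [tuple(sorted(s)) for s in sets]

    set_bits = []
    for s in sets:
        bits = [index[t] for t in s]
        set_bits.append((s, bits, sum(1 << b for b in bits)))

    counts = {s: [0, 0, 0] for s, _b, _m in set_bits}
    for tree in sample.trees:
        present, edges = tree.splits(index)
        for s, bits, mask in set_bits:
            if present & mask != mask:
                continue
            split = None
            sups: list[Optional[float]] = []
            for emask, sup in edges:
                if (emask & mask).bit_count() != 2:
                    continue  # restriction of this bipartition uninformative
                in_pair = [i for i, b in enumerate(bits) if emask >> b & 1]
                # which split: the pair containing the smallest taxon decides
                if 0 in in_pair:
                    q = in_pair[0] + in_pair[1] - 1  # {0,1}->0 {0,2}->1 {0,3}->2
                else:
                    q = {frozenset((2, 3)): 0, frozenset((1, 3)): 1,
                         frozenset((1, 2)): 2}[frozenset(in_pair)]
                split = q
                sups.append(sup)
            if split is None:
                continue  # unresolved on these 4 taxa
            if support_threshold is not None:
                # best annotated support among edges inducing the split;
                # a gene without any support annotation passes
                numeric = [s for s in sups if s is not None]
                if numeric and max(numeric) < support_threshold:
                    continue
            counts[s][split] += 1

    records = []
    for s, _b, _m in set_bits:
        x = counts[s]
        n = sum(x)
        if n == 0:
            continue
        records.append(QuartetCFRecord(s, tuple(v / n for v in x), ngenes=n))
    return QuartetCFTable(records)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_CF_COLS = ("CF12_34", "CF13_24", "CF14_23")


def write_cf_table(table: QuartetCFTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_cf_table(path) -> QuartetCFTable:
    df = pd.read_csv(path)
    need = ["taxon1", "taxon2", "taxon3", "taxon4", *_CF_COLS]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"CF table missing columns {missing}")
    has_bounds = all(c + suf in df.columns for c in _CF_COLS
                     for suf in ("_lo", "_hi"))
    records = []
    for _, row in df.iterrows():
        taxa = tuple(sorted(str(row[f"taxon{i}"]) for i in range(1, 5)))
        if tuple(str(row[f"taxon{i}"]) for i in range(1, 5)) != taxa:
            raise ValueError(f"taxa not in canonical sorted order: {taxa}")
        cf = tuple(float(row[c]) for c in _CF_COLS)
        lo = hi = None
        if has_bounds:
            lo = tuple(float(row[c + "_lo"]) for c in _CF_COLS)
            hi = tuple(float(row[c + "_hi"]) for c in _CF_COLS)
        ngenes = float(row["ngenes"]) if "ngenes" in df.columns \
            and not pd.isna(row.get("ngenes")) else None
        records.append(QuartetCFRecord(taxa, cf, ngenes=ngenes, lo=lo, hi=hi))
    return QuartetCFTable(records)


# ---------------------------------------------------------------------------
# concordance prior and CI-based resampling
# ---------------------------------------------------------------------------

def concordance_prior(alpha: float) -> float:
    """Prior probability that two genes share the same quartet tree under a
    Dirichlet-process concordance prior with concentration alpha:
    (1 + alpha/3) / (1 + alpha).  alpha -> inf gives the by-chance 1/3."""
    if alpha < 0:
        raise ValueError(f"negative alpha {alpha}")
    if math.isinf(alpha):
        return 1.0 / 3.0
    return (1.0 + alpha / 3.0) / (1.0 + alpha)


def resample_cf_table(table: QuartetCFTable, seed: Optional[int] = None
                      ) -> QuartetCFTable:
    """One bootstrap table: each CF drawn uniformly from its 95% credibility
    interval, then the three draws renormalized to sum to 1."""
    if not table.has_bounds():
        raise ValueError("resampling requires credibility bounds on every record")
    rng = np.random.default_rng(seed)
    records = []
    for r in table.records:
        draw = [rng.uniform(a, b) if b > a else float(a)
                for a, b in zip(r.lo, r.hi)]
        s = sum(draw)
        cf = tuple(d / s for d in draw)
        records.append(QuartetCFRecord(r.taxa, cf, ngenes=r.ngenes))
    return QuartetCFTable(records)
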