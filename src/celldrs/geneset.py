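"""Construction and interactome expansion of the esophageal-malformation gene set.

The curated (primary) gene set combines three evidence tracks: genome-wide
association hits, genes implicated through animal models of esophageal
anomalies, and genes found by exome sequencing of patients.  The set is then
expanded through a protein-protein interaction network (STRING-export TSV
dialect) by adding up to a fixed number of high-confidence interactors in one
or more "shells": shell 1 holds direct neighbours of the curated genes,
shell 2 neighbours of the enlarged set, and so on.

Every symbol carries a provenance tag (``gwas``, ``animal_model``, ``exome``,
``interactor_shell1``, ``interactor_shell2``, ...) so downstream tables can
distinguish curated genes from interactome additions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneSet",
    "InteractionTable",
    "load_primary_genes",
    "expand_with_interactors",
    "em_primary_geneset",
    "read_gene_list",
    "read_gene_table",
    "PRIMARY_GWAS_GENES",
    "PRIMARY_ANIMAL_MODEL_GENES",
    "PRIMARY_EXOME_GENES",
]

# Curated esophageal-malformation genes, by evidence track.
PRIMARY_GWAS_GENES = ("CTNNA3", "FOXF1", "FOXC2", "FOXL1", "HNF1B")

PRIMARY_ANIMAL_MODEL_GENES = (
    "MTHFSD", "MID1", "MKKS", "SHH", "GLI2", "GLI3", "NOGGIN", "NKX2-1",
    "EFTUD2", "SOX2", "ADD1", "GLS", "AP1G2", "TECPR1", "KLHL17", "CELSR2",
    "DISP1", "SMAD6",
)

PRIMARY_EXOME_GENES = ("APC2", "AMER3", "PCDH1", "GTF3C1", "RAB3GAP2", "ITSN1")


def _normalize_symbol(token: str) -> str:
    sym = token.strip().upper()
    if not sym:
        raise ValueError("blank gene symbol in input list")
    return sym


@dataclass
class GeneSet:
    """A named, provenance-tagged ordered set of gene symbols.

    Symbols are uppercase-normalized and unique; ``source`` maps every symbol
    to exactly one provenance tag.
    """

    name: str
    symbols: list[str]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            dupes = sorted({s for s in self.symbols if self.symbols.count(s) > 1})
            raise ValueError(f"duplicate symbols in gene set {self.name!r}: {dupes}")
        missing = [s for s in self.symbols if s not in self.source]
        if missing:
            raise ValueError(f"symbols without provenance tag: {missing}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.source

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"symbol": self.symbols, "source": [self.source[s] for s in self.symbols]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str = "geneset") -> "GeneSet":
        symbols = [_normalize_symbol(s) for s in frame["symbol"]]
        return cls(name=name, symbols=symbols,
                   source=dict(zip(symbols, frame["source"].astype(str))))


class InteractionTable:
    """Undirected protein-protein interactions with combined confidence scores.

    Scores live in [0, 1]; duplicate unordered pairs collapse to the maximum
    score and self-edges are rejected.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        scores: dict[tuple[str, str], float] = {}
        for a, b, s in edges:
            a, b = _normalize_symbol(a), _normalize_symbol(b)
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"combined score {s} outside [0, 1] for {a}-{b}")
            key = (a, b) if a < b else (b, a)
            scores[key] = max(s, scores.get(key, 0.0))
        if not scores:
            raise ValueError("interaction table is empty")
        self._scores = scores
        self._adj: dict[str, dict[str, float]] = {}
        for (a, b), s in scores.items():
            self._adj.setdefault(a, {})[b] = s
            self._adj.setdefault(b, {})[a] = s

    def __len__(self) -> int:
        return len(self._scores)

    def neighbors(self, symbol: str) -> dict[str, float]:
        return dict(self._adj.get(symbol, {}))

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adj)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionTable":
        """Read a STRING-export TSV: columns protein1, protein2, combined_score.

        Raw STRING scores are integers in 0-1000; fractional scores are also
        accepted.  The dialect is auto-detected from the maximum score.
        """
        frame = pd.read_csv(path, sep=r"\s+", comment="#")
        cols = {c.lower(): c for c in frame.columns}
        try:
            p1, p2, cs = cols["protein1"], cols["protein2"], cols["combined_score"]
        except KeyError as exc:
            raise ValueError(
                f"{path}: expected columns protein1, protein2, combined_score; "
                f"found {list(frame.columns)}"
            ) from exc
        scores = frame[cs].astype(float)
        if scores.max() > 1.0:  # raw STRING integers 0-1000
            scores = scores / 1000.0
        return cls(zip(frame[p1].astype(str), frame[p2].astype(str), scores))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self._scores.items())
        return pd.DataFrame(
            {"protein1": [k[0] for k, _ in rows],
             "protein2": [k[1] for k, _ in rows],
             "combined_score": [s for _, s in rows]}
        )


def load_primary_genes(
    lists: Mapping[str, Sequence[str]], name: str = "primary"
) -> GeneSet:
    """Merge labeled symbol lists into one provenance-tagged gene set.

    ``lists`` maps a source tag (e.g. ``gwas``) to an ordered symbol list.
    The result is the deduplicated union in first-occurrence order; a symbol
    appearing under two sources keeps the first and triggers a warning.
    """
    symbols: list[str] = []
    source: dict[str, str] = {}
    for tag, raw_list in lists.items():
        for token in raw_list:
            sym = _normalize_symbol(token)
            if sym in source:
                if source[sym] != tag:
                    warnings.warn(
                        f"{sym} listed under both {source[sym]!r} and {tag!r}; "
                        f"keeping {source[sym]!r}",
                        stacklevel=2,
                    )
                continue
            symbols.append(sym)
            source[sym] = tag
    if not symbols:
        raise ValueError("all input gene lists are empty")
    return GeneSet(name=name, symbols=symbols, source=source)


def em_primary_geneset() -> GeneSet:
    """The 29 curated esophageal-malformation genes (GWAS + animal model + exome)."""
    return load_primary_genes(
        {
            "gwas": PRIMARY_GWAS_GENES,
            "animal_model": PRIMARY_ANIMAL_MODEL_GENES,
            "exome": PRIMARY_EXOME_GENES,
        },
        name="em_primary",
    )


def expand_with_interactors(
    seed: GeneSet,
    net: InteractionTable,
    min_score: float = 0.7,
    max_per_shell: int = 20,
    n_shells: int = 2,
) -> GeneSet:
    """Expand a gene set with high-confidence network interactors, shell by shell.

    Shell 1 adds up to ``max_per_shell`` non-seed genes connected to the seed
    set by an edge with combined score >= ``min_score``, ranked by their best
    edge score into the current set (ties broken lexicographically).  Each
    further shell applies the same rule to the neighbours of the previous
    shell's additions (the frontier), so a gene passed over by an earlier
    shell's cap is not reconsidered unless a newly added gene links to it.
    If shell 1 finds no qualifying interactor the seed is returned unchanged
    with a warning.
    """
    if not (0.0 < min_score <= 1.0):
        raise ValueError(f"min_score must lie in (0, 1], got {min_score}")
    if n_shells < 1:
        raise ValueError(f"n_shells must be >= 1, got {n_shells}")
    if max_per_shell < 0:
        raise ValueError(f"max_per_shell must be >= 0, got {max_per_shell}")

    symbols = list(seed.symbols)
    source = dict(seed.source)
    members = set(symbols)
    frontier = set(symbols)

    for shell in range(1, n_shells + 1):
        candidates = set()
        for m in frontier:
            candidates.update(nb for nb, s in net.neighbors(m).items()
                              if nb not in members and s >= min_score)
        best: dict[str, float] = {}
        for nb in candidates:
            best[nb] = max(s for m, s in net.neighbors(nb).items()
                           if m in members and s >= min_score)
        picks = sorted(best, key=lambda g: (-best[g], g))[:max_per_shell]
        if not picks:
            if shell == 1:
                warnings.warn(
                    f"no interactor of {seed.name!r} meets score >= {min_score}; "
                    "returning the seed set unchanged",
                    stacklevel=2,
                )
            break
        tag = f"interactor_shell{shell}"
        for g in picks:
            symbols.append(g)
            source[g] = tag
        members.update(picks)
        frontier = set(picks)

    return GeneSet(name=f"{seed.name}+interactors", symbols=symbols, source=source)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list: one symbol per line, '#' starts a comment."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            symbols.append(_normalize_symbol(token))
    return symbols


def read_gene_table(path: str | Path, name: str = "geneset") -> GeneSet:
    """Read a two-column TSV (symbol, source) into a GeneSet."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"symbol", "source"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns 'symbol' and 'source'")
    return GeneSet.from_frame(frame, name=name)
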