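"""Lexical resources: psycholinguistic norms, word vectors, taxonomy, syllables.

Three resources back feature extraction:

* a norms table (word -> concreteness, imageability, familiarity on 1-7
  scales, log10 frequency per million, phoneme count);
* a word-vector lexicon in word2vec text format;
* a hypernym taxonomy (child -> parent edges rooted at ``entity``) plus
  an explicit word -> node mapping.  The mapping replaces machine
  translation into an English taxonomy: callers state directly which
  taxonomy node(s) each lemma denotes.

Out-of-vocabulary behavior is uniform: lookups return None (with a
warning at load/lookup sites), never raise, and downstream features
become undefined when every token is OOV.  Imputation would fabricate
data.

The syllabifier implements standard Spanish orthographic rules and is
used to validate stimulus sets (the bundled 10 stimuli span 1-3
syllables).
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from semnav.ingest import casefold_lemma

logger = logging.getLogger(__name__)

NORM_COLUMNS = ("concreteness", "imageability", "familiarity", "log_frequency", "length")
#: 1-7 rating scales; log_frequency and length are open-ended.
SCALE_COLUMNS = ("concreteness", "imageability", "familiarity")

ROOT = "entity"

STRONG_VOWELS = set("aeoáéó")
WEAK_VOWELS = set("iuü")
ACCENTED_WEAK = set("íú")
ALL_VOWELS = STRONG_VOWELS | WEAK_VOWELS | ACCENTED_WEAK


@dataclass
class NormsTable:
    """word -> five psycholinguistic norms; lookups are case-folded, accent-preserving."""

    table: pd.DataFrame  # index: word; columns: NORM_COLUMNS
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def lookup(self, lemma: str) -> Optional[pd.Series]:
        key = casefold_lemma(lemma)
        if key in self.table.index:
            return self.table.loc[key]
        return None

    def __contains__(self, lemma: str) -> bool:
        return casefold_lemma(lemma) in self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VectorLexicon:
    """word -> fixed-dimension real vector with skip-with-warning OOV policy."""

    vectors: dict[str, np.ndarray]
    dim: int

    def lookup(self, word: str) -> Optional[np.ndarray]:
        return self.vectors.get(casefold_lemma(word))

    def __contains__(self, word: str) -> bool:
        return casefold_lemma(word) in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass
class Taxonomy:
    """Child->parent DAG rooted at 'entity' with a word -> node(s) mapping."""

    graph: nx.DiGraph  # edges point child -> parent
    mapping: dict[str, tuple[str, ...]]  # word -> candidate nodes (polysemy)
    dropped_nodes: tuple[str, ...] = ()

    def depth(self, node: str) -> Optional[int]:
        """Shortest parent-path edge count from node to the root, or None."""
        if node not in self.graph:
            return None
        try:
            return nx.shortest_path_length(self.graph, node, ROOT)
        except nx.NetworkXNoPath:  # pragma: no cover - unreachable nodes are dropped at load
            return None

    def word_depth(self, word: str, polysemy: str = "min") -> Optional[float]:
        """Depth for a word; multiple senses resolved by min (default) or mean."""
        nodes = self.mapping.get(casefold_lemma(word))
        if not nodes:
            return None
        depths = [d for d in (self.depth(n) for n in nodes) if d is not None]
        if not depths:
            return None
        return float(min(depths)) if polysemy == "min" else float(np.mean(depths))


def load_norms(path: str | Path) -> NormsTable:
    """Load and validate a norms CSV (word + the five norm columns).

    Rows with out-of-range scale values (outside [1, 7]) or non-positive
    length are rejected and reported in ``NormsTable.rejected``.

    Raises
    ------
    ValueError
        on a duplicate word (after case folding) or a non-numeric norm.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("word",) + NORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"norms file missing columns: {missing}")
    if df.empty:
        return NormsTable(table=df.set_index("word")[list(NORM_COLUMNS)])
    df["word"] = df["word"].map(casefold_lemma)
    dups = df["word"][df["word"].duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate norm word(s): {sorted(set(dups))}")
    for col in NORM_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric {col} in rows {bad}") from exc
    in_range = np.ones(len(df), dtype=bool)
    for col in SCALE_COLUMNS:
        in_range &= (df[col] >= 1) & (df[col] <= 7)
    in_range &= df["length"] >= 1
    rejected = df.loc[~in_range]
    if len(rejected):
        logger.warning("load_norms: rejected %d out-of-range rows: %s",
                       len(rejected), rejected["word"].tolist())
    table = df.loc[in_range].set_index("word")[list(NORM_COLUMNS)]
    return NormsTable(table=table, rejected=rejected)


def load_vectors(path: str | Path) -> VectorLexicon:
    """Load a word2vec text-format lexicon ('V d' header, then word + d floats).

    Duplicate words keep the first occurrence with a warning; a dimension
    mismatch on any line raises with the line number.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec header must be 'vocab_size dim'")
        _, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(
                    f"line {lineno}: expected {dim} components, got {len(values)}"
                )
            key = casefold_lemma(word)
            if key in vectors:
                logger.warning("load_vectors: duplicate word %r at line %d; keeping first", word, lineno)
                continue
            vec = np.asarray([float(v) for v in values], dtype=np.float64)
            if not np.any(vec):
                logger.warning("load_vectors: zero vector for %r skipped", word)
                continue
            vectors[key] = vec
    return VectorLexicon(vectors=vectors, dim=dim)


def load_taxonomy(edges_path: str | Path, mapping_path: str | Path) -> Taxonomy:
    """Load a child->parent TSV edge list and a word->node TSV mapping.

    Validates acyclicity and the presence of the root 'entity'; nodes
    that cannot reach the root are reported and dropped.  A word mapping
    to several nodes keeps all senses.
    """
    graph = nx.DiGraph()
    with open(edges_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            graph.add_edge(child.strip(), parent.strip())
    if ROOT not in graph:
        raise ValueError(f"taxonomy has no root node {ROOT!r}")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"taxonomy contains a cycle: {cycle}")
    reachable = set(nx.ancestors(graph, ROOT)) | {ROOT}
    dropped = tuple(sorted(set(graph.nodes) - reachable))
    if dropped:
        logger.warning("load_taxonomy: dropped %d nodes unreachable from root: %s",
                       len(dropped), list(dropped))
        graph.remove_nodes_from(dropped)
    mapping: dict[str, list[str]] = {}
    with open(mapping_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, node = line.split("\t")
            key = casefold_lemma(word.strip())
            node = node.strip()
            if node not in graph:
                logger.warning("load_taxonomy: mapping target %r not in taxonomy; skipped", node)
                continue
            mapping.setdefault(key, [])
            if node not in mapping[key]:
                mapping[key].append(node)
    return Taxonomy(graph=graph, mapping={k: tuple(v) for k, v in mapping.items()},
                    dropped_nodes=dropped)


def syllabify(word: str) -> int:
    """Count syllable nuclei of a Spanish orthographic word.

    Rules: strong vowels (a, e, o, accented or not) each nucleate;
    adjacent weak vowels (i, u) attach to a neighboring strong vowel as
    diphthongs unless accented (í, ú force hiatus); a run of only
    unaccented weak vowels is a single nucleus; the silent 'u' of 'qu' /
    'gu' before e/i does not nucleate.

    Raises
    ------
    ValueError
        on empty or non-alphabetic input.
    """
    w = unicodedata.normalize("NFC", word.strip().lower())
    if not w or not all(ch.isalpha() for ch in w):
        raise ValueError(f"syllabify expects an alphabetic word, got {word!r}")
    # strip silent u in que/qui/gue/gui (but not güe/güi)
    chars = []
    i = 0
    while i < len(w):
        if w[i] in "qg" and i + 2 < len(w) and w[i + 1] == "u" and w[i + 2] in "eiéí":
            chars.append(w[i])
            i += 2  # skip the silent u
            continue
        chars.append(w[i])
        i += 1
    s = "".join(chars)
    count = 0
    i = 0
    n = len(s)
    while i < n:
        if s[i] not in ALL_VOWELS:
            i += 1
            continue
        j = i
        while j < n and s[j] in ALL_VOWELS:
            j += 1
        cluster = s[i:j]
        nuclei = sum(1 for ch in cluster if ch in STRONG_VOWELS or ch in ACCENTED_WEAK)
        count += max(nuclei, 1)
        i = j
    if count == 0:
        raise ValueError(f"no syllable nucleus found in {word!r}")
    return count
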