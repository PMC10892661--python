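"""Genotype classification and phylogenetics for pmoA amplicons.

Reads are assigned to genotypes with a k-mer naive-Bayes classifier in the
style of the RDP/mothur classifiers: a genotype's evidence for a k-mer word
is the fraction of its reference sequences containing that word (with a
pseudocount), a read's score is the summed log evidence over its k-mers, and
confidence comes from bootstrap resampling one eighth of the read's k-mers.

Representative sequences are related by neighbor-joining trees built from
p-distances, with bootstrap support computed by resampling alignment
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from sipseek import _seq
from sipseek.simulate import ReadSet, ReferenceDB

UNCLASSIFIED = "unclassified"


# --------------------------------------------------------------------------
# naive-Bayes classifier
# --------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Trained k-mer naive-Bayes model.

    ``log_prob`` holds log P(word | genotype) for every possible k-mer code
    (row) and genotype (column, lexicographic order).  Priors are uniform and
    kept for reference; they add a constant per genotype and do not change
    the ranking.
    """

    k: int
    genotypes: tuple[str, ...]        # lexicographically sorted
    log_prob: np.ndarray              # (4**k, n_genotypes) float32
    priors: np.ndarray
    n_refs: dict[str, int]

    def word_probability(self, word: str, genotype: str) -> float:
        """P(word | genotype) for a k-mer given as a DNA string."""
        if len(word) != self.k:
            raise ValueError(f"word must have length k={self.k}")
        code = int(_kmer_codes(_seq.encode(word), self.k)[0, 0])
        g = self.genotypes.index(genotype)
        return float(np.exp(self.log_prob[code, g]))


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers, per row of a code matrix."""
    windows = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return windows.astype(np.int64) @ powers


def train_classifier(db: ReferenceDB, k: int = 8) -> ClassifierModel:
    """Train the classifier on a reference database.

    For genotype g with n_g references, P(word | g) =
    (number of references of g containing the word + 0.5) / (n_g + 1),
    the RDP-style word evidence with a 0.5 pseudocount.  Training is
    deterministic.
    """
    if not db.genotypes:
        raise ValueError("reference database is empty")
    if k < 1 or k > 10:
        raise ValueError("k must lie in [1, 10]")
    if k > db.length:
        raise ValueError("k exceeds the reference sequence length")
    genotypes = tuple(sorted(db.genotypes))
    n_words = 4 ** k
    log_prob = np.empty((n_words, len(genotypes)), dtype=np.float32)
    n_refs = {}
    for gi, g in enumerate(genotypes):
        refs = _seq.encode(db.sequences[g])
        n_g = len(refs)
        n_refs[g] = n_g
        contain = np.zeros(n_words, dtype=np.int64)
        kmers = _kmer_codes(refs, k)
        for row in kmers:
            contain[np.unique(row)] += 1
        log_prob[:, gi] = np.log((contain + 0.5) / (n_g + 1.0)).astype(np.float32)
    priors = np.full(len(genotypes), 1.0 / len(genotypes))
    return ClassifierModel(k=k, genotypes=genotypes, log_prob=log_prob,
                           priors=priors, n_refs=n_refs)


@dataclass
class Assignment:
    """A single read's genotype call with bootstrap confidence (0-100%)."""

    read_id: str
    genotype: str
    confidence: float

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 100:
            raise ValueError("confidence must lie in [0, 100]")


def _as_code_matrix(reads) -> tuple[np.ndarray, list[str]]:
    if isinstance(reads, ReadSet):
        return reads.codes, list(reads.ids)
    if isinstance(reads, np.ndarray):
        return reads, [f"read{i:06d}" for i in range(len(reads))]
    seqs = list(reads)
    return _seq.encode(seqs), [f"read{i:06d}" for i in range(len(seqs))]


def classify_reads(
    reads,
    model: ClassifierModel,
    n_bootstrap: int = 100,
    confidence_cutoff: float = 80.0,
    seed: int | None = 20240211,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Classify a batch of equal-length reads.

    Returns a DataFrame with columns ``read_id``, ``genotype`` and
    ``confidence``.  The called genotype maximizes the summed log word
    evidence; exact score ties go to the lexicographically smallest genotype
    name.  Confidence is the percentage of ``n_bootstrap`` resamples of
    ceil(m/8) of the read's m k-mers that agree with the call; replicate
    ties are broken uniformly at random.  Calls below ``confidence_cutoff``
    are reported as ``unclassified``.
    """
    codes, ids = _as_code_matrix(reads)
    if codes.shape[1] < model.k:
        raise ValueError("reads shorter than k cannot be classified")
    rng = np.random.default_rng(seed)
    n, g = len(codes), len(model.genotypes)
    m = codes.shape[1] - model.k + 1
    mb = math.ceil(m / 8)

    best = np.empty(n, dtype=np.int64)
    confidence = np.empty(n, dtype=float)
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        kc = _kmer_codes(codes[lo:hi], model.k)          # (B, m)
        pos_scores = model.log_prob[kc]                  # (B, m, g) float32
        scores = pos_scores.sum(axis=1, dtype=np.float64)
        b = np.argmax(scores, axis=1)                    # first max = lex smallest
        best[lo:hi] = b
        if n_bootstrap > 0:
            # one set of resampled k-mer positions per chunk; each read's
            # replicates remain i.i.d. uniform draws over its positions
            pos = rng.integers(0, m, size=(n_bootstrap, mb))
            bscores = pos_scores[:, pos, :].sum(axis=2, dtype=np.float32)  # (B, nb, g)
            bscores += rng.random(bscores.shape, dtype=np.float32) * 1e-3
            bbest = np.argmax(bscores, axis=2)           # (B, nb)
            confidence[lo:hi] = 100.0 * (bbest == b[:, None]).mean(axis=1)
        else:
            confidence[lo:hi] = 100.0
    names = np.array(model.genotypes, dtype=object)[best]
    names[confidence < confidence_cutoff] = UNCLASSIFIED
    return pd.DataFrame({"read_id": ids, "genotype": names, "confidence": confidence})


def classify_read(
    read: str,
    model: ClassifierModel,
    n_bootstrap: int = 100,
    confidence_cutoff: float = 80.0,
    seed: int | None = 20240211,
    read_id: str = "read",
) -> Assignment:
    """Classify a single read; see :func:`classify_reads`."""
    if len(read) < model.k:
        raise ValueError("read shorter than k")
    df = classify_reads([read], model, n_bootstrap=n_bootstrap,
                        confidence_cutoff=confidence_cutoff, seed=seed)
    row = df.iloc[0]
    return Assignment(read_id=read_id, genotype=str(row["genotype"]),
                      confidence=float(row["confidence"]))


def assignment_counts(assignments: pd.DataFrame, drop_unclassified: bool = True) -> dict[str, int]:
    """Read counts per called genotype, excluding unclassified reads by default."""
    counts = assignments["genotype"].value_counts().to_dict()
    if drop_unclassified:
        counts.pop(UNCLASSIFIED, None)
    return counts


# --------------------------------------------------------------------------
# distances and neighbor-joining
# --------------------------------------------------------------------------

def p_distance(a: str, b: str) -> float:
    """Fraction of sites at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        raise ValueError("sequences must be non-empty")
    ca, cb = _seq.encode(a), _seq.encode(b)
    return float((ca != cb).mean())


def distance_matrix(alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distance matrix of an alignment (name -> sequence)."""
    names, seqs = _alignment_items(alignment)
    codes = _seq.encode(seqs)
    diff = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    return diff, names


def _alignment_items(alignment) -> tuple[list[str], list[str]]:
    if isinstance(alignment, dict):
        items = list(alignment.items())
    else:
        items = [tuple(x) for x in alignment]
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("taxon names must be unique")
    return names, [s for _, s in items]


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    ``supports`` maps each internal bipartition (the canonical tip-name side,
    the one not containing the reference tip) to a support percentage.
    """

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self.tree.tips()))

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits induced by internal edges, canonicalized."""
        tips = set(t.name for t in self.tree.tips())
        ref = min(tips)
        splits = set()
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(tips - side)
            if 2 <= len(side) <= len(tips) - 2:
                splits.add(side)
        return splits

    def to_newick(self, path=None):
        """Newick string (bootstrap supports as internal node labels)."""
        out = self.tree.copy()
        if self.supports:
            tips = set(t.name for t in out.tips())
            ref = min(tips)
            for node in out.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(tips - side)
                if side in self.supports:
                    node.name = str(int(round(self.supports[side])))
        newick = str(out)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(newick if newick.endswith("\n") else newick + "\n")
        return newick


def _validate_distances(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def nj_tree(distances, names: list[str] | None = None) -> PhyloTree:
    """Neighbor-joining tree by the Saitou-Nei agglomeration.

    Deterministic: ties in the Q criterion are resolved by the lowest
    (row, column) index pair in the current matrix; negative branch lengths
    are clamped to zero.  The result is unrooted, represented with a
    trifurcating root.
    """
    d = _validate_distances(distances).copy()
    n = d.shape[0]
    if names is None:
        names = [f"t{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names must match the matrix size")
    nodes: list[TreeNode] = [TreeNode(name=str(nm)) for nm in names]

    while len(nodes) > 3:
        n_act = len(nodes)
        r = d.sum(axis=1)
        q = (n_act - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(n_act, k=1)
        flat = q[iu]
        pick = int(np.argmin(flat))      # first minimum: lowest (i, j) pair
        i, j = int(iu[0][pick]), int(iu[1][pick])

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n_act - 2))
        lj = d[i, j] - li
        a, b = nodes[i], nodes[j]
        a.length = max(float(li), 0.0)
        b.length = max(float(lj), 0.0)
        parent = TreeNode(children=[a, b])

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(n_act) if x not in (i, j)]
        d_new = np.empty((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-way join: three-point formulas
    (x, y, z) = nodes
    lx = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    ly = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lz = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in zip((x, y, z), (lx, ly, lz)):
        node.length = max(float(ln), 0.0)
    root = TreeNode(children=[x, y, z])
    return PhyloTree(tree=root)


def bootstrap_supports(alignment, n_reps: int = 1000, seed: int | None = 20240211) -> PhyloTree:
    """Neighbor-joining tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times, a NJ
    tree is rebuilt per replicate, and each internal bipartition of the
    original tree receives the percentage of replicates containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    names, seqs = _alignment_items(alignment)
    if len(names) < 4:
        raise ValueError("need at least 4 taxa for bootstrap supports")
    codes = _seq.encode(seqs)
    n_cols = codes.shape[1]

    d, _ = distance_matrix(alignment)
    result = nj_tree(d, names)
    counts = {split: 0 for split in result.bipartitions()}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = codes[:, cols]
        d_rep = (sub[:, None, :] != sub[None, :, :]).mean(axis=2)
        rep = nj_tree(d_rep, names)
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    result.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return result
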