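"""Alignment/tree/table I/O and alignment quality control.

The pipeline consumes in-frame codon multiple sequence alignments (FASTA),
phylogenetic trees (Newick) and flat annotation tables (TSV).  Quality control
follows the two-stage protocol used for the clock-gene alignments: first drop
sequences with excessive gaps (more than 5% of the alignment length or more
than 100 gap bases), then drop sequences whose agreement with the column
consensus falls below 40%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codons import STOP_CODONS
from .errors import (
    AlignmentError,
    DegenerateAlignmentError,
    FrameError,
    InputError,
    TreeParseError,
)

GAP = "-"
_VALID_CHARS = set("ACGTN-")


@dataclass(frozen=True)
class CodonAlignment:
    """A species-labelled, in-frame nucleotide multiple sequence alignment.

    Invariants (enforced at construction): all sequences equal length, length
    divisible by 3, unique taxon labels, alphabet {A,C,G,T,N,-}.
    """

    gene_id: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences must have equal length")
        if len(self.taxa) == 0:
            raise InputError("empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths in {self.gene_id}: {sorted(lengths)}"
            )
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(
                f"alignment length {length} of {self.gene_id} is not divisible by 3"
            )
        bad = set("".join(self.sequences).upper()) - _VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in {self.gene_id}: {sorted(bad)}")
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        object.__setattr__(self, "taxa", tuple(self.taxa))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0])

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def subset(self, taxa) -> "CodonAlignment":
        taxa = list(taxa)
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(
            self.gene_id, tuple(taxa), tuple(self.sequences[i] for i in idx)
        )

    def char_matrix(self) -> np.ndarray:
        """(n_taxa, length_nt) array of single characters."""
        return np.array([list(s) for s in self.sequences])


def _check_internal_stops(aln: CodonAlignment) -> None:
    for taxon, seq in zip(aln.taxa, aln.sequences):
        for k in range(aln.n_codons - 1):
            codon = seq[3 * k : 3 * k + 3]
            if codon in STOP_CODONS:
                warnings.warn(
                    f"{aln.gene_id}/{taxon}: internal stop codon {codon} at codon "
                    f"{k + 1}; treated as missing data downstream",
                    stacklevel=3,
                )


def read_codon_alignment(path, gene_id: str | None = None) -> CodonAlignment:
    """Read an in-frame codon alignment from a FASTA file.

    Internal stop codons are reported as warnings (they become missing data in
    the likelihood machinery), not errors; structural problems (ragged
    lengths, broken reading frame, empty file) raise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    if gene_id is None:
        gene_id = str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    aln = CodonAlignment(
        gene_id=gene_id,
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )
    _check_internal_stops(aln)
    return aln


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


def prune_gappy_sequences(
    aln: CodonAlignment,
    max_gap_frac: float = 0.05,
    max_gap_count: int = 100,
) -> CodonAlignment:
    """Drop sequences with gap fraction > max_gap_frac OR gap count > max_gap_count.

    'N' counts as an ambiguous base, not a gap.  Columns are never removed.
    """
    if not 0 <= max_gap_frac <= 1:
        raise ValueError("max_gap_frac must be in [0, 1]")
    keep_taxa, keep_seqs = [], []
    for taxon, seq in zip(aln.taxa, aln.sequences):
        gaps = seq.count(GAP)
        if gaps / aln.length_nt > max_gap_frac or gaps > max_gap_count:
            continue
        keep_taxa.append(taxon)
        keep_seqs.append(seq)
    if len(keep_seqs) < 2:
        raise DegenerateAlignmentError(
            f"{aln.gene_id}: fewer than 2 sequences remain after gap pruning"
        )
    return replace(aln, taxa=tuple(keep_taxa), sequences=tuple(keep_seqs))


def consensus_scores(aln: CodonAlignment) -> np.ndarray:
    """Per-sequence agreement with the column-majority residue.

    The majority residue of a column is the most frequent A/C/G/T (ties broken
    alphabetically; gaps and N never win).  A sequence's score is the fraction
    of its A/C/G/T positions that match the majority of their column.
    """
    chars = aln.char_matrix()
    counts = np.stack([(chars == nt).sum(axis=0) for nt in "ACGT"])  # (4, L)
    majority = np.array(list("ACGT"))[counts.argmax(axis=0)]  # argmax = ties→'A' first
    valid = np.isin(chars, list("ACGT"))
    match = (chars == majority[None, :]) & valid
    denom = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        scores = np.where(denom > 0, match.sum(axis=1) / np.maximum(denom, 1), 0.0)
    return scores


def consensus_filter(aln: CodonAlignment, min_consensus: float = 0.40) -> CodonAlignment:
    """Drop sequences whose consensus score is below min_consensus."""
    scores = consensus_scores(aln)
    keep = scores >= min_consensus
    if not keep.any():
        raise DegenerateAlignmentError(
            f"{aln.gene_id}: every sequence fell below consensus {min_consensus}"
        )
    return replace(
        aln,
        taxa=tuple(t for t, k in zip(aln.taxa, keep) if k),
        sequences=tuple(s for s, k in zip(aln.sequences, keep) if k),
    )


def qc_alignment(
    aln: CodonAlignment,
    max_gap_frac: float = 0.05,
    max_gap_count: int = 100,
    min_consensus: float = 0.40,
) -> CodonAlignment:
    """Full QC: gap pruning first, then the consensus filter."""
    return consensus_filter(
        prune_gappy_sequences(aln, max_gap_frac, max_gap_count), min_consensus
    )


# --- trees -----------------------------------------------------------------


def read_tree(path) -> dendropy.Tree:
    """Parse a Newick tree; missing branch lengths become 0 with a warning."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"malformed Newick in {path}: {exc}") from exc
    _fill_missing_lengths(tree, str(path))
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    _fill_missing_lengths(tree, "<string>")
    return tree


def _fill_missing_lengths(tree: dendropy.Tree, source: str) -> None:
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
        elif edge.length < 0:
            raise TreeParseError(f"negative branch length in {source}")
    if missing:
        warnings.warn(
            f"{source}: {missing} branch length(s) missing, set to 0", stacklevel=3
        )


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# --- annotation tables -----------------------------------------------------


def read_go_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, term_id, namespace."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "namespace"}
    if not required.issubset(df.columns):
        raise InputError(f"GO table {path} must have columns {sorted(required)}")
    if df["gene_id"].isna().any() or (df["gene_id"] == "").any():
        raise InputError(f"GO table {path} contains empty gene ids")
    return df


def read_interaction_table(path) -> pd.DataFrame:
    """TSV with columns gene_a, gene_b and optional source.

    Duplicate undirected edges (including the same edge from several sources)
    collapse to one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_a", "gene_b"}.issubset(df.columns):
        raise InputError(f"interaction table {path} must have gene_a/gene_b columns")
    return dedupe_interactions(df)


def dedupe_interactions(df: pd.DataFrame) -> pd.DataFrame:
    lo = df[["gene_a", "gene_b"]].min(axis=1)
    hi = df[["gene_a", "gene_b"]].max(axis=1)
    out = pd.DataFrame({"gene_a": lo, "gene_b": hi})
    if "source" in df.columns:
        out["source"] = df["source"].values
    return out.drop_duplicates(subset=["gene_a", "gene_b"]).reset_index(drop=True)
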