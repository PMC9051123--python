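"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention); VCF positions are converted from 1-based on ingestion.
Motif count matrices use the fixed column order A, C, G, T.  Writers emit
rows in lexicographic key order so outputs are byte-deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}" if path else message)
        self.path = path
        self.line = line


@dataclass
class MotifMatrix:
    """A position count matrix with columns in A,C,G,T order."""

    motif_id: str
    tf_names: list[str]
    counts: np.ndarray  # L x 4, non-negative
    pseudocount: float = 0.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: counts must be L x 4")
        if self.counts.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: empty matrix")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if self.pseudocount < 0:
            raise ValueError(f"{self.motif_id}: negative pseudocount")
        if ((self.counts + self.pseudocount).sum(axis=1) <= 0).any():
            raise ValueError(f"{self.motif_id}: zero column sum after pseudocount")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def probabilities(self, bg_composition: np.ndarray | None = None,
                      pseudocount_fraction: float = 0.01) -> np.ndarray:
        """Per-position base probabilities with a composition-weighted pseudocount.

        The pseudocount added to each row is ``pseudocount_fraction`` times the
        row's count total, distributed across bases proportionally to
        ``bg_composition`` (uniform when not given).
        """
        comp = (np.full(4, 0.25) if bg_composition is None
                else np.asarray(bg_composition, float) / np.sum(bg_composition))
        row_tot = self.counts.sum(axis=1, keepdims=True)
        pseudo = pseudocount_fraction * row_tot * comp[None, :]
        probs = self.counts + pseudo
        return probs / probs.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with an optional strand and label."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"bad strand {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class InteractionNetwork:
    """Undirected protein-protein interaction network.

    Direction and sign in source files are treated as metadata: first-neighbour
    expansion only needs interactors, so A-B and B-A collapse to one edge.
    """

    graph: nx.Graph
    source_tag: str = ""
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}


def _motif_from_bio(m, fallback_id: str) -> MotifMatrix:
    counts = np.array([[m.counts[b][i] for b in ALPHABET]
                       for i in range(m.length)], dtype=float)
    # TRANSFAC records are dict-like (AC/ID keys); JASPAR motifs carry
    # matrix_id / name attributes
    accession = m.get("AC") if isinstance(m, dict) else None
    name = (m.get("ID") if isinstance(m, dict) else None) or m.name
    motif_id = getattr(m, "matrix_id", None) or accession or name or fallback_id
    return MotifMatrix(motif_id=str(motif_id), tf_names=[name] if name else [],
                       counts=counts)


def _prevalidate_jaspar(path: Path) -> None:
    # Bio.motifs error messages do not carry line numbers; check row shapes first.
    expected = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                expected = None
                continue
            row = s.replace("[", " ").replace("]", " ").split()
            if row and row[0] in "ACGT":
                row = row[1:]
            try:
                vals = [float(v) for v in row]
            except ValueError:
                raise ParseError("non-numeric count", path, lineno)
            if expected is None:
                expected = len(vals)
            elif len(vals) != expected:
                raise ParseError(
                    f"row has {len(vals)} values, expected {expected}", path, lineno)


def read_motifs(path, format: str = "jaspar") -> list[MotifMatrix]:
    """Read a JASPAR or TRANSFAC motif file into count matrices.

    Motif order in the file is preserved.
    """
    path = Path(path)
    if format not in ("jaspar", "transfac"):
        raise ValueError(f"unknown motif format {format!r}")
    if format == "jaspar":
        _prevalidate_jaspar(path)
    with open(path) as fh:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                parsed = list(bio_motifs.parse(fh, format))
        except ParseError:
            raise
        except Exception as exc:  # Bio raises assorted ValueErrors
            raise ParseError(str(exc), path) from exc
    out = [_motif_from_bio(m, f"motif_{i + 1}") for i, m in enumerate(parsed)]
    if not out:
        raise ParseError("no motifs found", path)
    return out


def write_motifs(ms: list[MotifMatrix], path, format: str = "transfac") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for m in ms:
            name = m.tf_names[0] if m.tf_names else m.motif_id
            if format == "jaspar":
                fh.write(f">{m.motif_id} {name}\n")
                for j, b in enumerate(ALPHABET):
                    vals = " ".join(f"{v:g}" for v in m.counts[:, j])
                    fh.write(f"{b} [ {vals} ]\n")
            elif format == "transfac":
                fh.write(f"AC  {m.motif_id}\nXX\nID  {name}\nXX\n")
                fh.write("P0      A      C      G      T\n")
                for i in range(len(m)):
                    row = "".join(f"{v:7g}" for v in m.counts[i])
                    fh.write(f"{i + 1:02d} {row}\n")
                fh.write("XX\n//\n")
            else:
                raise ValueError(f"unknown motif format {format!r}")


def read_network(path, dialect: str = "sif", id_map: dict[str, str] | None = None,
                 self_loops: str = "drop", source_tag: str = "") -> InteractionNetwork:
    """Read a SIF or two-column TSV edge list as an undirected network.

    Unmappable endpoints (when ``id_map`` is given) are recorded on the
    returned object's ``skipped`` list rather than raising.
    """
    path = Path(path)
    g = nx.Graph()
    skipped: list[tuple[str, str]] = []

    def add_edge(a: str, b: str):
        if id_map is not None:
            ma, mb = id_map.get(a), id_map.get(b)
            if ma is None or mb is None:
                skipped.append((a, b))
                return
            a, b = ma, mb
        if a == b:
            if self_loops == "keep":
                g.add_edge(a, b)
            else:
                g.add_node(a)
            return
        g.add_edge(a, b)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if dialect == "sif":
                if len(parts) == 1:
                    g.add_node(parts[0])
                elif len(parts) >= 3:
                    for tgt in parts[2:]:
                        add_edge(parts[0], tgt)
                else:
                    raise ParseError("SIF row needs 1 or >=3 columns", path, lineno)
            elif dialect == "tsv2col":
                if len(parts) < 2:
                    raise ParseError("need two endpoint columns", path, lineno)
                add_edge(parts[0], parts[1])
            else:
                raise ValueError(f"unknown network dialect {dialect!r}")
    if g.number_of_nodes() == 0:
        log.warning("network file %s is empty", path)
    if skipped:
        log.warning("%d edges skipped (unmappable IDs) in %s", len(skipped), path)
    return InteractionNetwork(graph=g, source_tag=source_tag or path.name,
                              skipped=skipped)


def write_network(net: InteractionNetwork, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(nx.isolates(net.graph)):
            fh.write(f"{n}\n")


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file: term, description, then member genes."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if len(parts) < 3:
                raise ParseError("GMT row needs term, description, >=1 gene",
                                 path, lineno)
            term = parts[0]
            if term in out:
                raise ParseError(f"duplicate term {term!r}", path, lineno)
            out[term] = {g for g in parts[2:] if g}
    return out


def write_gene_sets(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{term}\t{genes}\n")


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV, or MTX with .rows/.cols sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        mat = np.asarray(mmread(path).todense())
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise ParseError("duplicated gene or sample IDs", path)
    if (df.values < 0).any():
        raise ParseError("negative counts", path)
    return df


_CARRIER = {"0/0": False, "0|0": False}


def _gt_to_carrier(gt: str):
    """Any alternate allele makes a carrier; './.' is missing (None)."""
    if gt in _CARRIER:
        return _CARRIER[gt]
    alleles = gt.replace("|", "/").split("/")
    if all(a == "." for a in alleles):
        return None
    return any(a not in ("0", ".") for a in alleles)


def read_genotypes(path) -> pd.DataFrame:
    """Read per-patient carrier status from a VCF or TSV.

    Returns a patients x SNPs DataFrame of {True, False, <NA>} (boolean dtype
    with missing).  TSV input has a ``patient`` index column and 0/1/NA cells.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        import pysam
        rows: dict[str, dict[str, object]] = {}
        rsids: list[str] = []
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
            if len(samples) != len(set(samples)):
                raise ParseError("duplicated sample IDs", path)
            for rec in vf:
                rsid = rec.id or f"{rec.chrom}:{rec.pos}"
                rsids.append(rsid)
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None:
                        carrier = None
                    else:
                        carrier = (None if all(a is None for a in gt)
                                   else any(a not in (0, None) for a in gt))
                    rows.setdefault(s, {})[rsid] = carrier
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(columns=rsids, index=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ParseError("duplicated patient IDs", path)
        df = df.map(lambda v: None if pd.isna(v) else bool(int(v)))
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.warning("%d missing genotypes treated as non-carrier", n_missing)
    return df.astype("boolean")


def read_regions(path) -> list[GenomicInterval]:
    """Read a BED / BED-like TSV into intervals (name -> label, col 6 -> strand)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise ParseError("BED row needs chrom, start, end", path, lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-integer coordinates", path, lineno)
            label = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            try:
                out.append(GenomicInterval(parts[0], start, end, strand, label))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno)
    return out


def write_regions(intervals: list[GenomicInterval], path) -> None:
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.label))
    with open(path, "w") as fh:
        for iv in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t0\t{iv.strand}\n")


def read_enhancer_map(path) -> dict[str, set[str]]:
    """Two-column TSV mapping enhancer label -> target gene."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ParseError("need enhancer and gene columns", path, lineno)
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def read_id_map(path) -> dict[str, str]:
    """Two-column TSV gene -> protein accession map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 2:
                raise ParseError("need source and target ID columns", path, lineno)
            out[parts[0]] = parts[1]
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
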