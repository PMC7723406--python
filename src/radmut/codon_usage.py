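"""Effective number of codons (Wright's Nc).

The ENC measures how far codon usage departs from uniform use of synonymous
codons: 20 means a single codon per amino acid (maximal bias), 61 means all
synonymous codons equally used (standard code).  It is used here as a screen
for selection on codon usage — a moderate, radioactivity-independent ENC
supports the synonymous substitution rate as a mutation-rate proxy.

For an amino acid with k synonymous codons observed N times with codon
frequencies p_c, the homozygosity estimator is

    F_hat = (N * sum p_c^2 - 1) / (N - 1),

class means F_k are taken over amino acids sharing degeneracy k, and for the
standard code

    ENC = 2 + 9/F_2 + 1/F_3 + 5/F_4 + 3/F_6,

capped at the number of sense codons.  Alternative genetic codes (e.g. the
invertebrate mitochondrial code) are supported via NCBI code tables; the
degeneracy classes are then derived from that code.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Mapping

import numpy as np
from Bio.Data import CodonTable
from Bio import SeqIO


class CodonUsageError(ValueError):
    """Invalid codon-count input."""


def genetic_code(table_id: int = 1) -> CodonTable.CodonTable:
    """An NCBI genetic code table (1 = standard, 5 = invertebrate mito)."""
    return CodonTable.unambiguous_dna_by_id[table_id]


def _families(code: CodonTable.CodonTable) -> dict[str, list[str]]:
    fam: dict[str, list[str]] = defaultdict(list)
    for codon, aa in code.forward_table.items():
        fam[aa].append(codon)
    return fam


def count_codons(sequences: Iterable[str], table_id: int = 1) -> Counter:
    """Codon counts from in-frame coding sequences; stop and ambiguous
    codons are skipped."""
    code = genetic_code(table_id)
    sense = set(code.forward_table)
    counts: Counter = Counter()
    for seq in sequences:
        s = str(seq).upper().replace("U", "T")
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if codon in sense:
                counts[codon] += 1
    return counts


def enc(codon_counts: Mapping[str, int], table_id: int = 1) -> float:
    """Wright's effective number of codons from a codon-count table.

    Amino acids observed fewer than twice are skipped from their class mean.
    A degeneracy class with no usable amino acid is imputed by Wright's
    fallback (the 3-fold class as the mean of the 2- and 4-fold class means;
    any other empty class as 1/k-interpolated from the available classes is
    not attempted — an error is raised instead).  The result is capped at
    the code's number of sense codons.
    """
    counts = {c.upper(): int(n) for c, n in codon_counts.items() if int(n) != 0}
    if any(n < 0 for n in counts.values()):
        raise CodonUsageError("codon counts must be nonnegative")
    code = genetic_code(table_id)
    sense = set(code.forward_table)
    unknown = set(counts) - sense
    if unknown:
        raise CodonUsageError(
            f"non-sense or invalid codons for code table {table_id}: {sorted(unknown)}"
        )
    if not counts:
        raise CodonUsageError("empty codon-count table")

    families = _families(code)
    n_single = sum(1 for codons in families.values() if len(codons) == 1)
    f_hat_by_k: dict[int, list[float]] = defaultdict(list)
    class_counts: Counter = Counter(
        len(codons) for codons in families.values() if len(codons) > 1
    )
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            continue
        n_aa = sum(counts.get(c, 0) for c in codons)
        if n_aa < 2:
            continue  # F_hat undefined at N < 2
        p = np.array([counts.get(c, 0) / n_aa for c in codons])
        f_hat = (n_aa * float((p**2).sum()) - 1.0) / (n_aa - 1.0)
        if f_hat > 0:
            f_hat_by_k[k].append(f_hat)

    f_bar: dict[int, float] = {
        k: float(np.mean(v)) for k, v in f_hat_by_k.items() if v
    }
    # Wright's fallback for the (single-amino-acid) 3-fold class
    if 3 in class_counts and 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = 0.5 * (f_bar[2] + f_bar[4])
    missing = [k for k in class_counts if k not in f_bar]
    if missing:
        raise CodonUsageError(
            f"no amino acid with >=2 observations in degeneracy class(es) {missing}"
        )
    value = n_single + sum(class_counts[k] / f_bar[k] for k in class_counts)
    return float(min(value, len(sense)))


def enc_from_fasta(
    path,
    table_id: int = 1,
    per_gene: bool = False,
) -> float | dict[str, float]:
    """ENC of in-frame coding sequences in a FASTA file.

    With ``per_gene=False`` (default) codons are pooled over all records
    (concatenated mode); with ``per_gene=True`` a per-record ENC dict is
    returned, leaving the averaging to the caller.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise CodonUsageError(f"no sequences in {path}")
    if per_gene:
        return {
            rec.id: enc(count_codons([str(rec.seq)], table_id), table_id)
            for rec in records
        }
    return enc(count_codons((str(r.seq) for r in records), table_id), table_id)
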