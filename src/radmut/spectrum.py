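"""Sister-pair polymorphism orientation and mutational-spectrum estimation.

Within a pair of closely related species, a site where the two species share
exactly one allele is polarised by parsimony: the shared allele is taken as
ancestral and every other allele carried by either species is a derived
(mutant) allele of that species.  Directed mutation counts are corrected by
the ancestral base frequency,

    p(i->j | f(i)anc) = N(i->j) / N_anc(i),

then normalised by the sum over all twelve directed rates to obtain the
mutational spectrum p(i->j | mu, f(i)anc), a proportion conditional on a
mutation having occurred and therefore comparable across species with
different mutation rates.  Complementary directed mutations are pooled after
normalisation into six strand-symmetric classes (e.g. C->A with G->T into
C:G->A:T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Strand-symmetric pooled mutation classes, in canonical order.
POOLED_CLASSES = (
    "C:G>A:T",
    "A:T>T:A",
    "C:G>T:A",
    "A:T>C:G",
    "C:G>G:C",
    "A:T>G:C",
)

#: Directed mutation (i, j) -> pooled class label.
DIRECTED_TO_CLASS = {}
for _cls in POOLED_CLASSES:
    _src, _dst = _cls.split(">")
    _i, _j = _src.split(":")[0], _dst.split(":")[0]
    DIRECTED_TO_CLASS[(_i, _j)] = _cls
    DIRECTED_TO_CLASS[(COMPLEMENT[_i], COMPLEMENT[_j])] = _cls

#: Pooled class -> {ancestral base: derived base}; resolving a pooled class
#: against a fixed ancestral base is deterministic because the two directed
#: mutations in a class have complementary (hence distinct) source bases.
CLASS_TO_DERIVED = {cls: {} for cls in POOLED_CLASSES}
for (_i, _j), _cls in DIRECTED_TO_CLASS.items():
    CLASS_TO_DERIVED[_cls][_i] = _j

ORIENTED = "oriented"
DISCARDED_NO_SHARED = "discarded_no_shared"
DISCARDED_AMBIGUOUS = "discarded_ambiguous"


class SpectrumError(ValueError):
    """Invalid input to orientation or spectrum estimation."""


@dataclass
class OrientedSite:
    """A site polarised (or discarded) by the shared-allele parsimony rule."""

    gene_id: str
    site_index: int
    codon_position: int
    status: str
    ancestral_base: str | None = None
    derived_by_species: dict = field(default_factory=dict)


@dataclass
class MutationCounts:
    """Directed mutation counts and ancestral-base totals.

    ``n_dir[i, j]`` counts derived-allele records with ancestral base i and
    derived base j (indices into ACGT); ``n_anc[i]`` counts oriented sites
    whose ancestral base is i, monomorphic shared sites included — the
    correction denominator is the ancestral base frequency over all analysed
    sites, not over polymorphic ones.
    """

    n_dir: np.ndarray
    n_anc: np.ndarray
    position_filter: str = "all"

    def __post_init__(self) -> None:
        self.n_dir = np.asarray(self.n_dir, dtype=float)
        self.n_anc = np.asarray(self.n_anc, dtype=float)
        if self.n_dir.shape != (4, 4) or self.n_anc.shape != (4,):
            raise SpectrumError("n_dir must be 4x4 and n_anc length 4")
        if (self.n_dir < 0).any() or (self.n_anc < 0).any():
            raise SpectrumError("mutation counts must be nonnegative")
        row_tot = self.n_dir.sum(axis=1)
        if (row_tot > 0).any() and (self.n_anc[row_tot > 0] == 0).any():
            raise SpectrumError("N(i->j) > 0 with N_anc(i) = 0")


@dataclass
class MutationalSpectrum:
    """Ancestral-frequency-corrected, normalised, complement-pooled spectrum."""

    p_dir: np.ndarray        # 4x4, p(i->j | f(i)anc); diagonal 0
    p_norm: np.ndarray       # 4x4, normalised to sum 1 over the 12 entries
    p_pooled: np.ndarray     # length 6, order of POOLED_CLASSES
    position_filter: str = "all"

    def pooled_as_series(self) -> pd.Series:
        return pd.Series(self.p_pooled, index=list(POOLED_CLASSES))


@dataclass
class PairContrast:
    """Per-pair log-ratio of pooled proportions, high- over low-exposure."""

    pair_id: str
    pi: np.ndarray                       # length 6; NaN where undefined
    delta_covariate: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def _check_alleles(alleles: Iterable[str], label: str) -> frozenset:
    s = frozenset(alleles)
    if not s:
        raise SpectrumError(f"empty allele set for {label}")
    bad = s - set(BASES)
    if bad:
        raise SpectrumError(f"invalid allele(s) {sorted(bad)} for {label}")
    return s


def orient_site(alleles_a: Iterable[str], alleles_b: Iterable[str]):
    """Polarise one site from the allele sets of the two species of a pair.

    Returns ``(status, ancestral_base, derived_a, derived_b)``.  If the two
    sets share exactly one allele it is ancestral and every other allele of
    each species is derived for that species; no shared allele or more than
    one shared allele discards the site.
    """
    set_a = _check_alleles(alleles_a, "species A")
    set_b = _check_alleles(alleles_b, "species B")
    shared = set_a & set_b
    if len(shared) == 0:
        return DISCARDED_NO_SHARED, None, (), ()
    if len(shared) > 1:
        return DISCARDED_AMBIGUOUS, None, (), ()
    (anc,) = shared
    derived_a = tuple(sorted(set_a - shared))
    derived_b = tuple(sorted(set_b - shared))
    return ORIENTED, anc, derived_a, derived_b


def orient_pair_table(
    table: pd.DataFrame,
    species_a: str,
    species_b: str,
) -> list[OrientedSite]:
    """Orient every site present in both species of a pair.

    ``table`` is a site-allele table (see :func:`read_site_allele_table`);
    sites covered in only one species are skipped because orientation needs
    both.
    """
    required = {"species", "gene_id", "site_index", "codon_position", "alleles"}
    missing = required - set(table.columns)
    if missing:
        raise SpectrumError(f"site-allele table missing columns {sorted(missing)}")
    sub = table[table["species"].isin([species_a, species_b])]
    wide = sub.pivot_table(
        index=["gene_id", "site_index", "codon_position"],
        columns="species",
        values="alleles",
        aggfunc="first",
    )
    if species_a not in wide.columns or species_b not in wide.columns:
        raise SpectrumError(
            f"species {species_a!r} and/or {species_b!r} absent from table"
        )
    wide = wide.dropna(subset=[species_a, species_b])
    out: list[OrientedSite] = []
    for (gene, site, cpos), row in wide.iterrows():
        try:
            status, anc, der_a, der_b = orient_site(row[species_a], row[species_b])
        except SpectrumError as exc:
            raise SpectrumError(f"{exc} (gene {gene}, site {site})") from exc
        derived = {}
        if status == ORIENTED:
            derived = {species_a: list(der_a), species_b: list(der_b)}
        out.append(
            OrientedSite(
                gene_id=gene,
                site_index=int(site),
                codon_position=int(cpos),
                status=status,
                ancestral_base=anc,
                derived_by_species=derived,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Counting and the spectrum
# ---------------------------------------------------------------------------

def count_mutations(
    oriented_sites: Sequence[OrientedSite],
    position_filter: str = "all",
    species: str | None = None,
) -> MutationCounts:
    """Tally directed mutations and ancestral-base totals over oriented sites.

    ``position_filter`` is ``"all"`` or ``"third"`` (codon position 3 only).
    ``species`` selects whose derived alleles are counted; ``None`` counts
    the derived records of every species in ``derived_by_species`` (useful
    for pair-pooled tallies).  N_anc always counts each oriented site once.
    """
    if position_filter not in ("all", "third"):
        raise SpectrumError(f"unknown position filter {position_filter!r}")
    n_dir = np.zeros((4, 4))
    n_anc = np.zeros(4)
    for site in oriented_sites:
        if site.status != ORIENTED:
            raise SpectrumError("count_mutations expects oriented sites only")
        if position_filter == "third" and site.codon_position != 3:
            continue
        i = BASE_INDEX[site.ancestral_base]
        n_anc[i] += 1
        if species is None:
            derived = [b for lst in site.derived_by_species.values() for b in lst]
        else:
            derived = site.derived_by_species.get(species, [])
        for b in derived:
            n_dir[i, BASE_INDEX[b]] += 1
    return MutationCounts(n_dir=n_dir, n_anc=n_anc, position_filter=position_filter)


def normalized_spectrum(counts: MutationCounts) -> MutationalSpectrum:
    """Compute p(i->j|f(i)anc), its normalisation, and the pooled 6-vector.

    Pooling is applied after normalisation: each pooled entry is the sum of
    the two complementary normalised directed proportions.
    """
    if counts.n_dir.sum() == 0:
        raise SpectrumError("all mutation counts are zero; spectrum undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        p_dir = np.where(counts.n_anc[:, None] > 0, counts.n_dir / counts.n_anc[:, None], 0.0)
    np.fill_diagonal(p_dir, 0.0)
    total = p_dir.sum()
    p_norm = p_dir / total
    p_pooled = np.zeros(len(POOLED_CLASSES))
    for (i, j), cls in DIRECTED_TO_CLASS.items():
        p_pooled[POOLED_CLASSES.index(cls)] += p_norm[BASE_INDEX[i], BASE_INDEX[j]]
    return MutationalSpectrum(
        p_dir=p_dir,
        p_norm=p_norm,
        p_pooled=p_pooled,
        position_filter=counts.position_filter,
    )


def pooled_counts(counts: MutationCounts) -> np.ndarray:
    """Raw directed mutation counts summed into the six pooled classes.

    These are the count vectors the habitat chi-square tests operate on
    (counts, not the ancestral-frequency-corrected proportions).
    """
    out = np.zeros(len(POOLED_CLASSES))
    for (i, j), cls in DIRECTED_TO_CLASS.items():
        out[POOLED_CLASSES.index(cls)] += counts.n_dir[BASE_INDEX[i], BASE_INDEX[j]]
    return out


def species_spectrum(
    table: pd.DataFrame,
    species: str,
    partner: str,
    position_filter: str = "all",
) -> MutationalSpectrum:
    """Spectrum of one species, oriented against its sister-pair partner."""
    sites = orient_pair_table(table, species, partner)
    oriented = [s for s in sites if s.status == ORIENTED]
    counts = count_mutations(oriented, position_filter=position_filter, species=species)
    return normalized_spectrum(counts)


def pair_spectra(
    table: pd.DataFrame,
    species_a: str,
    species_b: str,
    position_filter: str = "all",
) -> dict:
    """Orient a pair once and return each species' counts and spectrum.

    Returns ``{species: (MutationCounts, MutationalSpectrum)}``.
    """
    sites = orient_pair_table(table, species_a, species_b)
    oriented = [s for s in sites if s.status == ORIENTED]
    out = {}
    for sp in (species_a, species_b):
        counts = count_mutations(oriented, position_filter=position_filter, species=sp)
        out[sp] = (counts, normalized_spectrum(counts))
    return out


def pair_contrast(
    spectrum_high: MutationalSpectrum,
    spectrum_low: MutationalSpectrum,
    log_base: float = math.e,
    pair_id: str = "",
    delta_covariate: Mapping[str, float] | None = None,
) -> PairContrast:
    """Per-class log ratio pi = log(p_high / p_low) of pooled proportions.

    A class with a zero proportion in either species yields NaN (undefined)
    rather than an exception.
    """
    ph = np.asarray(spectrum_high.p_pooled, dtype=float)
    pl = np.asarray(spectrum_low.p_pooled, dtype=float)
    pi = np.full(len(POOLED_CLASSES), np.nan)
    ok = (ph > 0) & (pl > 0)
    pi[ok] = np.log(ph[ok] / pl[ok]) / math.log(log_base)
    return PairContrast(
        pair_id=pair_id,
        pi=pi,
        delta_covariate=dict(delta_covariate or {}),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ["species", "gene_id", "site_index", "codon_position", "alleles"]


def read_site_allele_table(path) -> pd.DataFrame:
    """Read a site-allele TSV (species, gene_id, site_index, codon_position,
    alleles — the allele set as a sorted string such as ``AT``)."""
    df = pd.read_csv(path, sep="\t", dtype={"alleles": str, "gene_id": str})
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SpectrumError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["alleles"].str.fullmatch(r"[ACGT]+")
    if bad.any():
        row = df[bad].iloc[0]
        raise SpectrumError(
            f"{path}: invalid alleles {row['alleles']!r} "
            f"(species {row['species']}, gene {row['gene_id']}, site {row['site_index']})"
        )
    return df


def write_site_allele_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SITE_TABLE_COLUMNS)


def site_table_from_alignments(
    alignments: Mapping[str, Mapping[str, str]],
    species_of: callable,
) -> pd.DataFrame:
    """Build a site-allele table from per-gene multi-individual alignments.

    ``alignments`` maps gene_id -> {sequence_id: aligned sequence}; sequences
    of one gene must share a length that is a multiple of 3 (codon-aware
    alignment).  ``species_of`` maps a sequence id to its species.  The
    allele set at a site is the set of bases observed across the individuals
    of a species; gaps and ambiguity codes are excluded, and sites where a
    species shows no unambiguous base are omitted for that species.  Codon
    positions cycle 1, 2, 3 along the alignment.
    """
    rows = []
    for gene_id, seqs in alignments.items():
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise SpectrumError(f"gene {gene_id}: unequal sequence lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise SpectrumError(f"gene {gene_id}: alignment length {length} not a multiple of 3")
        by_species: dict[str, list[str]] = {}
        for seq_id, seq in seqs.items():
            by_species.setdefault(species_of(seq_id), []).append(seq.upper())
        for sp, sp_seqs in by_species.items():
            for pos in range(length):
                alleles = {s[pos] for s in sp_seqs} & set(BASES)
                if alleles:
                    rows.append(
                        (sp, gene_id, pos, pos % 3 + 1, "".join(sorted(alleles)))
                    )
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def spectrum_table(spectra: Mapping[str, MutationalSpectrum]) -> pd.DataFrame:
    """One row per (species, position filter) with the six pooled proportions."""
    rows = []
    for sp, spec in spectra.items():
        rows.append(
            {"species": sp, "position_filter": spec.position_filter}
            | dict(zip(POOLED_CLASSES, spec.p_pooled))
        )
    return pd.DataFrame(rows)


def contrast_table(contrasts: Sequence[PairContrast]) -> pd.DataFrame:
    """One row per (pair, pooled class) with the log-ratio contrast."""
    rows = []
    for con in contrasts:
        for cls, val in zip(POOLED_CLASSES, con.pi):
            rows.append(
                {"pair_id": con.pair_id, "mutation_class": cls, "pi": val}
                | {f"delta_{k}": v for k, v in con.delta_covariate.items()}
            )
    return pd.DataFrame(rows)
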