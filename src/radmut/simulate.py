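"""Synthetic comparative data with the structure the analysis assumes.

The generator emulates a comparative design of subterranean waterlouse
species sampled in habitats of contrasted bedrock radioactivity: sister
species come in monophyletic pairs on an ultrametric chronogram, one member
of each pair in a low- and one in a high-radioactivity regime; three
collinear radioactivity proxies (sediment alpha activity in Bq/g, received
dose in uGy/h, and the areal proportion lambda15 of igneous/metamorphic
bedrock within 15 km); population polymorphism across a panel of orthologous
coding genes, with the C:G->A:T share of the mutation spectrum rising with
radioactivity; and tip substitution rates following Brownian motion on the
tree plus a covariate effect on the log scale.

Everything is reproducible from (config, seed).  Per-gene random streams are
derived from the master seed and the gene index, so changing the gene count
does not reshuffle earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from . import pgls
from .spectrum import (
    BASES,
    CLASS_TO_DERIVED,
    POOLED_CLASSES,
    SITE_TABLE_COLUMNS,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class InvalidEffectError(ValueError):
    """A spectrum shift that leaves the probability simplex."""


# stream ids for deterministic sub-seeding
_STREAM_TREE = 1
_STREAM_COVARIATES = 2
_STREAM_RATES = 3
_STREAM_SITES = 4


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic comparative data set.

    Defaults reproduce the design of the motivating study: 6 sister pairs
    plus 2 unpaired species (14 tips), a chronogram of depth 1 (root age
    rescaled to 1), 2490 orthologous genes, regime means 0.357 and 1.259
    Bq/g of dry sediment, and a transition-biased baseline spectrum whose
    C:G->A:T class shifts additively with log alpha radioactivity.
    """

    n_pairs: int = 6
    n_extra: int = 2
    tree_depth: float = 1.0
    n_genes: int = 2490
    sites_per_gene: int = 45
    theta: float = 0.01
    base_composition: tuple = (0.28, 0.22, 0.22, 0.28)   # A, C, G, T
    baseline_spectrum: tuple = (0.10, 0.08, 0.32, 0.08, 0.08, 0.34)
    spectrum_effect: float = 0.013     # shift of C:G->A:T per unit log(Bq/g)
    covariate_low_mean: float = 0.357  # Bq/g
    covariate_high_mean: float = 1.259  # Bq/g
    covariate_cv: float = 0.25         # lognormal CV within a regime
    bm_sigma2: float = 0.05            # Brownian variance of log rate / time
    rate_beta: float = 0.22            # effect of log alpha on log(dS/ra)
    rate_root: float = 0.05            # nuclear dS/ra at zero covariate
    rate_beta_mito: float = 0.44       # mitochondrial effect, ~2x nuclear
    rate_root_mito: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.n_extra < 0:
            raise ConfigError("n_extra must be >= 0")
        if self.tree_depth <= 0:
            raise ConfigError("tree_depth must be positive")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigError("theta must lie in [0, 1]")
        if self.bm_sigma2 < 0:
            raise ConfigError("bm_sigma2 must be >= 0")
        for name, vec, size in (
            ("base_composition", self.base_composition, 4),
            ("baseline_spectrum", self.baseline_spectrum, 6),
        ):
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (size,):
                raise ConfigError(f"{name} must have length {size}")
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        if min(self.covariate_low_mean, self.covariate_high_mean) <= 0:
            raise ConfigError("regime means must be positive")

    def rng(self, *stream) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, *stream)))


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def pair_tip_labels(pair: int) -> tuple[str, str]:
    return f"pair{pair:02d}_a", f"pair{pair:02d}_b"


def pairs_from_labels(labels) -> list[tuple[str, str]]:
    """Recover the sister-pair structure from the tip naming convention."""
    pairs: dict[str, dict[str, str]] = {}
    for lab in labels:
        if lab.startswith("pair") and "_" in lab:
            pid, member = lab.rsplit("_", 1)
            pairs.setdefault(pid, {})[member] = lab
    out = []
    for pid in sorted(pairs):
        members = pairs[pid]
        if set(members) != {"a", "b"}:
            raise ConfigError(f"incomplete pair {pid}: members {sorted(members)}")
        out.append((members["a"], members["b"]))
    return out


def simulate_pair_tree(config: SimulationConfig) -> dendropy.Tree:
    """A rooted binary ultrametric tree with each sister pair as a cherry.

    Pair split times are drawn in the shallow part of the tree (5-35% of the
    depth) and the pair/unpaired lineages are then joined at deeper times,
    the final join at exactly ``tree_depth``, so all root-to-tip path
    lengths equal the depth by construction.
    """
    rng = config.rng(_STREAM_TREE)
    depth = config.tree_depth
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(label: str):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        node.height = 0.0
        return node

    subtrees = []
    for p in range(1, config.n_pairs + 1):
        a, b = pair_tip_labels(p)
        split = depth * rng.uniform(0.05, 0.35)
        anc = dendropy.Node()
        anc.height = split
        for child in (leaf(a), leaf(b)):
            anc.add_child(child)
            child.edge.length = split
        subtrees.append(anc)
    for q in range(1, config.n_extra + 1):
        subtrees.append(leaf(f"extra{q:02d}"))

    n_joins = len(subtrees) - 1
    if n_joins == 0:
        # a single pair: the cherry is the root, so ultrametricity forces the
        # split to sit at the full depth
        root = subtrees[0]
        root.height = depth
        for child in root.child_nodes():
            child.edge.length = depth
    else:
        times = np.sort(depth * rng.uniform(0.4, 1.0, size=n_joins))
        times[-1] = depth
        rng.shuffle(subtrees)
        while len(subtrees) > 1:
            i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
            right = subtrees.pop(j)
            left = subtrees.pop(i)
            t = times[n_joins - len(subtrees) - 1]
            parent = dendropy.Node()
            parent.height = t
            for child in (left, right):
                parent.add_child(child)
                child.edge.length = t - child.height
            subtrees.append(parent)
        root = subtrees[0]
    tree.seed_node = root
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def _lognormal_around(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def assign_covariates(tree: dendropy.Tree, config: SimulationConfig) -> pd.DataFrame:
    """Regime labels and collinear radioactivity proxies for every tip.

    One random member of each sister pair is assigned to the low and one to
    the high regime; unpaired tips alternate between regimes.  Alpha
    radioactivity is lognormal around the regime mean.  Received dose and
    lambda15 are monotone noisy functions of alpha (power law and logistic
    in log alpha, respectively), which makes the three proxies collinear as
    in real bedrock data; lambda15 is bounded in [0, 1] by the logistic
    form.
    """
    rng = config.rng(_STREAM_COVARIATES)
    labels = pgls.tip_labels(tree)
    pairs = pairs_from_labels(labels)
    if len(pairs) != config.n_pairs:
        raise ConfigError(
            f"tree has {len(pairs)} pairs, config expects {config.n_pairs}"
        )
    rows = []
    for pid, (tip_a, tip_b) in enumerate(pairs, start=1):
        low_first = rng.random() < 0.5
        regimes = ("low", "high") if low_first else ("high", "low")
        for tip, regime in zip((tip_a, tip_b), regimes):
            rows.append({"tip": tip, "pair_id": f"pair{pid:02d}", "regime": regime})
    extras = [l for l in labels if l.startswith("extra")]
    for i, tip in enumerate(sorted(extras)):
        rows.append(
            {"tip": tip, "pair_id": "", "regime": "low" if i % 2 == 0 else "high"}
        )
    df = pd.DataFrame(rows).set_index("tip")
    means = df["regime"].map(
        {"low": config.covariate_low_mean, "high": config.covariate_high_mean}
    )
    if config.covariate_cv == 0:
        alpha = means.to_numpy(dtype=float)
        rd_noise = np.zeros(len(df))
        lam_noise = np.zeros(len(df))
    else:
        alpha = np.array(
            [
                _lognormal_around(rng, m, config.covariate_cv, 1)[0]
                for m in means.to_numpy(dtype=float)
            ]
        )
        rd_noise = rng.normal(0.0, 0.25, size=len(df))
        lam_noise = rng.normal(0.0, 0.8, size=len(df))
    df["alpha_radio"] = alpha
    df["received_dose"] = 0.25 * alpha * np.exp(rd_noise)
    df["lambda15"] = 1.0 / (1.0 + np.exp(-(1.0 + 1.8 * np.log(alpha) + lam_noise)))
    return df.loc[labels]


# ---------------------------------------------------------------------------
# Mutational spectrum of a species
# ---------------------------------------------------------------------------

def spectrum_for_covariate(
    baseline_spectrum, spectrum_effect: float, covariate: float
) -> np.ndarray:
    """Shift the C:G->A:T class by effect*covariate; renormalise the rest.

    The other five classes are scaled down proportionally so the vector
    still sums to one.  A shift that drives any entry outside [0, 1] raises
    :class:`InvalidEffectError`.
    """
    q = np.asarray(baseline_spectrum, dtype=float)
    if q.shape != (6,) or (q < 0).any() or abs(q.sum() - 1.0) > 1e-12:
        raise ConfigError("baseline_spectrum must be a 6-class probability vector")
    shift = spectrum_effect * covariate
    target = q[0] + shift
    if not 0.0 <= target <= 1.0:
        raise InvalidEffectError(
            f"shifted C:G->A:T proportion {target:g} outside [0, 1]"
        )
    out = q.copy()
    rest = 1.0 - q[0]
    out[0] = target
    if rest > 0:
        out[1:] *= (1.0 - target) / rest
    elif target != 1.0:
        raise InvalidEffectError("cannot rescale: baseline puts all mass on C:G->A:T")
    return out


#: For each ancestral base, the pooled classes compatible with it (a class is
#: compatible when one of its two directed mutations starts from that base).
_COMPATIBLE = {
    b: [k for k, cls in enumerate(POOLED_CLASSES) if b in CLASS_TO_DERIVED[cls]]
    for b in BASES
}
_DERIVED_CODE = {
    (b, k): BASES.index(CLASS_TO_DERIVED[POOLED_CLASSES[k]][b])
    for b in BASES
    for k in _COMPATIBLE[b]
}


def expected_pooled_spectrum(spectrum) -> np.ndarray:
    """Expected pooled-class frequency of simulated mutations.

    Because the generator draws the pooled class conditionally on the
    classes compatible with the (already drawn) ancestral base, the marginal
    class frequency under uniform base composition is q_c / (2 S(c)) with
    S(c) the total generating mass of c's strand group; it equals q_c when
    the spectrum is strand-group balanced.
    """
    q = np.asarray(spectrum, dtype=float)
    s_cg = q[[0, 2, 4]].sum()
    s_at = q[[1, 3, 5]].sum()
    group = np.array([s_cg, s_at, s_cg, s_at, s_cg, s_at])
    return q / (2.0 * group)


def simulate_pair_polymorphism(
    pair: tuple[str, str],
    config: SimulationConfig,
    covariates: pd.DataFrame,
    pair_index: int = 0,
) -> pd.DataFrame:
    """Polymorphism site-allele table for the two species of one pair.

    Per gene and site an ancestral base is drawn from the base composition;
    each species is independently polymorphic with probability theta, and a
    polymorphic site receives one derived allele obtained by drawing a
    pooled mutation class from that species' spectrum restricted to the
    classes compatible with the ancestral base (the ancestral base then
    fixes the directed mutation).  Codon positions cycle 1, 2, 3.  Every
    analysed site appears in the table — monomorphic sites carry the
    single ancestral allele.
    """
    species = list(pair)
    species_spectra = {}
    for sp in species:
        cov = math.log(covariates.loc[sp, "alpha_radio"])
        species_spectra[sp] = spectrum_for_covariate(
            config.baseline_spectrum, config.spectrum_effect, cov
        )
    # per (species, ancestral base): cumulative probs over compatible classes
    comp = np.asarray(config.base_composition, dtype=float)
    reachable = [b for b, p in zip(BASES, comp) if p > 0]
    cond = {}
    for sp in species:
        q = species_spectra[sp]
        for b in reachable:
            idx = _COMPATIBLE[b]
            w = q[idx]
            tot = w.sum()
            if tot <= 0:
                raise ConfigError(
                    f"spectrum of {sp} has zero mass on classes compatible with {b}"
                )
            cond[(sp, b)] = (np.cumsum(w / tot), idx)

    # allele-set string lookup: monomorphic {anc} or sorted pair {anc, derived}
    mono_str = np.array(list(BASES))
    pair_str = np.array(
        [["".join(sorted((a, d))) for d in BASES] for a in BASES]
    )
    n_sites = config.sites_per_gene
    cols: dict[str, list] = {c: [] for c in SITE_TABLE_COLUMNS}
    site_idx = np.arange(n_sites)
    cpos = site_idx % 3 + 1
    for g in range(config.n_genes):
        rng = config.rng(_STREAM_SITES, pair_index, g)
        anc_idx = rng.choice(4, size=n_sites, p=comp)
        gene_id = f"g{g:05d}"
        for sp in species:
            poly = rng.random(n_sites) < config.theta
            u = rng.random(n_sites)
            der_idx = np.full(n_sites, -1)
            for bi, b in enumerate(BASES):
                mask = poly & (anc_idx == bi)
                if not mask.any():
                    continue
                cum, idx = cond[(sp, b)]
                pos = np.minimum(
                    np.searchsorted(cum, u[mask], side="right"), len(idx) - 1
                )
                classes = np.asarray(idx)[pos]
                der_idx[mask] = [ _DERIVED_CODE[(b, int(k))] for k in classes ]
            alleles = np.where(
                poly, pair_str[anc_idx, np.maximum(der_idx, 0)], mono_str[anc_idx]
            )
            cols["species"].append(np.repeat(sp, n_sites))
            cols["gene_id"].append(np.repeat(gene_id, n_sites))
            cols["site_index"].append(site_idx)
            cols["codon_position"].append(cpos)
            cols["alleles"].append(alleles)
    if not cols["species"]:
        return pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    return pd.DataFrame(
        {c: np.concatenate(v) for c, v in cols.items()}
    )[SITE_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Tip rates
# ---------------------------------------------------------------------------

def simulate_tip_rates(
    tree: dendropy.Tree,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    beta: float | None = None,
    root_rate: float | None = None,
    stream: int = 0,
) -> pd.Series:
    """Tip dS/ra: Brownian motion on the log scale plus a covariate effect.

    log(dS/ra) ~ MVN(log(root_rate) + beta * log(alpha_radio), sigma2 * V)
    with V the Brownian variance/covariance matrix of the tree.
    """
    if config.bm_sigma2 < 0:
        raise ConfigError("bm_sigma2 must be >= 0")
    beta = config.rate_beta if beta is None else beta
    root_rate = config.rate_root if root_rate is None else root_rate
    rng = config.rng(_STREAM_RATES, stream)
    labels = pgls.tip_labels(tree)
    V = pgls.brownian_vcv(tree, labels=labels).matrix
    mean = np.log(root_rate) + beta * np.log(
        covariates.loc[labels, "alpha_radio"].to_numpy(dtype=float)
    )
    if config.bm_sigma2 == 0:
        log_rate = mean
    else:
        L = np.linalg.cholesky(V)
        log_rate = mean + math.sqrt(config.bm_sigma2) * (L @ rng.standard_normal(len(labels)))
    return pd.Series(np.exp(log_rate), index=labels, name="ds_ra")


# ---------------------------------------------------------------------------
# Whole data sets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Tree, covariates (with tip rates) and per-pair polymorphism tables."""

    config: SimulationConfig
    tree: dendropy.Tree
    covariates: pd.DataFrame        # + ds_ra, ds_ra_mito columns
    sites: pd.DataFrame             # stacked site-allele table, all pairs
    pairs: list = field(default_factory=list)

    @property
    def newick(self) -> str:
        return pgls.tree_to_newick(self.tree)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic comparative data set."""
    tree = simulate_pair_tree(config)
    cov = assign_covariates(tree, config)
    cov["ds_ra"] = simulate_tip_rates(
        tree, cov, config, beta=config.rate_beta, root_rate=config.rate_root, stream=0
    )
    cov["ds_ra_mito"] = simulate_tip_rates(
        tree, cov, config, beta=config.rate_beta_mito,
        root_rate=config.rate_root_mito, stream=1,
    )
    pairs = pairs_from_labels(pgls.tip_labels(tree))
    tables = [
        simulate_pair_polymorphism(pair, config, cov, pair_index=i)
        for i, pair in enumerate(pairs)
    ]
    sites = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=SITE_TABLE_COLUMNS
    )
    return SimulatedDataset(config=config, tree=tree, covariates=cov, sites=sites,
                            pairs=pairs)


DATA_DICTIONARY = """\
column	table	description
tip	covariates	tip label matching the newick tree
pair_id	covariates	sister-pair identifier; empty for unpaired tips
regime	covariates	radioactivity regime, low or high
alpha_radio	covariates	sediment alpha radioactivity, Bq/g dry sediment
received_dose	covariates	biologically weighted dose rate, uGy/h
lambda15	covariates	areal proportion of igneous/metamorphic bedrock within 15 km, in [0,1]
ds_ra	covariates	nuclear synonymous substitution rate relative to root age
ds_ra_mito	covariates	mitochondrial synonymous substitution rate relative to root age
species	sites	species (tip) the allele set belongs to
gene_id	sites	orthologous gene identifier
site_index	sites	0-based site index within the gene alignment
codon_position	sites	codon position, 1-3
alleles	sites	observed allele set as a sorted string, e.g. AT
"""


def write_dataset(data: SimulatedDataset, outdir) -> dict:
    """Write tree, covariates, site table, config and data dictionary."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": out / "tree.nwk",
        "covariates": out / "covariates.tsv",
        "sites": out / "sites.tsv",
        "config": out / "config.yaml",
        "data_dictionary": out / "data_dictionary.tsv",
    }
    paths["tree"].write_text(data.newick + "\n")
    data.covariates.reset_index(names="tip").to_csv(
        paths["covariates"], sep="\t", index=False
    )
    data.sites.to_csv(paths["sites"], sep="\t", index=False)
    paths["config"].write_text(yaml.safe_dump(asdict(data.config), sort_keys=False))
    paths["data_dictionary"].write_text(DATA_DICTIONARY)
    return {k: str(v) for k, v in paths.items()}
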