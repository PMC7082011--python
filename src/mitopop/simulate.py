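"""Coalescent simulation of two-haplogroup mitochondrial datasets.

The generator emulates the structure a Macaronesian-style mitochondrial
survey assumes: a few hundred aligned control-region-like sequences
(~637 sites, strongly AT-biased), two deeply divergent haplogroups founded by
sequences a fixed number of mutations apart, each haplogroup carrying its own
expansion history, and opposing clinal haplogroup frequencies across the
sampled sites.  The truth record (haplogroup labels, expansion times,
cline) is kept so every downstream estimator can be scored.

Genealogies come from msprime (single non-recombining locus, haploid
samples).  Time is scaled so that one unit of branch length is one unit of
*mutational time*: with population size θ/2 and a per-sequence mutation rate
of 1, the expected pairwise difference count equals θ, and a sudden
expansion at mutational time τ before present matches the τ of mismatch
theory.  Mutations are dropped by this module, not msprime: the finite-sites
AT-biased model used here (draws from an equilibrium with
P(A)+P(T) = at_fraction) is what produces realistic base composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np
import pandas as pd
import tskit

from .errors import MitopopError
from .seqio import Alignment, make_alignment, write_alignment

BASES = "ACGT"


@dataclass(frozen=True)
class SuddenExpansion:
    """Instantaneous growth: size θ/ratio before mutational time tau, θ after."""

    tau: float
    ratio: float = 1000.0

    def __post_init__(self):
        if self.tau < 0 or self.ratio <= 0:
            raise MitopopError("sudden_expansion requires tau >= 0, ratio > 0")


def simulate_genealogy(
    n: int,
    theta: float,
    history="constant",
    seed: int | None = None,
) -> tskit.TreeSequence:
    """Simulate a single coalescent genealogy for ``n`` haploid samples.

    Branch lengths are in mutational-time units (see module docstring): a
    constant-size history has E[TMRCA of a pair] = θ/2, so the branch length
    separating a random pair has expectation θ.
    """
    if n < 2:
        raise MitopopError("n >= 2 required")
    if theta <= 0:
        raise MitopopError("theta > 0 required")
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=theta / 2.0)
    if history == "constant":
        pass
    elif isinstance(history, SuddenExpansion):
        # tau mutational units = tau/2 "generations" at per-sequence rate 1
        demography.add_population_parameters_change(
            time=history.tau / 2.0,
            initial_size=theta / (2.0 * history.ratio),
            population="pop",
        )
    else:
        raise MitopopError(f"unknown history: {history!r}")
    return msprime.sim_ancestry(
        samples={"pop": n},
        demography=demography,
        ploidy=1,
        sequence_length=1,
        discrete_genome=False,
        random_seed=None if seed is None else (seed % (2**31 - 2)) + 1,
    )


def _branch_table(tree: tskit.Tree) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """(branch_lengths, num_samples_below, node_ids) for non-root nodes."""
    nodes, bls, sizes = [], [], []
    for u in tree.nodes():
        bl = tree.branch_length(u)
        if bl > 0:
            nodes.append(u)
            bls.append(bl)
            sizes.append(tree.num_samples(u))
    return np.array(bls), np.array(sizes), nodes


def sprinkle_infinite_sites(
    ts: tskit.TreeSequence,
    rng: np.random.Generator,
    condition_on: str = "theta",
    S_fixed: int | None = None,
) -> tuple[int, float, int]:
    """Place infinite-sites mutations on a genealogy; return (S, θ̂_π, k).

    With ``condition_on="theta"`` each branch receives Poisson(length)
    mutations (per-sequence rate 1); with ``"S"`` exactly ``S_fixed``
    mutations are placed multinomially in proportion to branch length.
    Every mutation hits a fresh site, so S is the mutation count, θ̂_π
    accumulates i(n−i) pair differences per mutation of derived count i,
    and k is the number of leaf classes separated by ≥1 mutation.
    """
    tree = ts.first()
    n = ts.num_samples
    bls, sizes, nodes = _branch_table(tree)
    if condition_on == "theta":
        muts = rng.poisson(bls)
    elif condition_on == "S":
        if S_fixed is None:
            raise MitopopError("S_fixed required when conditioning on S")
        muts = rng.multinomial(S_fixed, bls / bls.sum())
    else:
        raise MitopopError("condition_on must be 'theta' or 'S'")

    S = int(muts.sum())
    pair_diffs = float(np.sum(muts * sizes * (n - sizes)))
    theta_pi = pair_diffs / (n * (n - 1) / 2.0)

    # haplotype classes: cut every branch carrying >= 1 mutation
    mut_count = dict(zip(nodes, muts))
    comp: dict[int, int] = {}
    next_comp = 0
    for u in tree.nodes(order="preorder"):
        parent = tree.parent(u)
        if parent == tskit.NULL or mut_count.get(u, 0) > 0:
            comp[u] = next_comp
            next_comp += 1
        else:
            comp[u] = comp[parent]
    k = len({comp[s] for s in ts.samples()})
    return S, theta_pi, k


def _draw_equilibrium(rng: np.random.Generator, L: int, at_fraction: float) -> np.ndarray:
    """Root sequence with exactly the target base composition, shuffled.

    Pinning the counts (rather than drawing each site independently) removes
    the ±1.5%-per-dataset composition noise a single 637-site multinomial
    draw would impose on every descendant sequence.
    """
    n_a = int(round(L * at_fraction / 2))
    n_t = int(round(L * at_fraction)) - n_a
    n_c = int(round(L * (1 - at_fraction) / 2))
    n_g = L - n_a - n_t - n_c
    seq = np.concatenate([
        np.zeros(n_a, dtype=int), np.full(n_c, 1), np.full(n_g, 2), np.full(n_t, 3),
    ])
    rng.shuffle(seq)
    return seq


def apply_mutations(
    ts: tskit.TreeSequence,
    L: int,
    at_fraction: float = 0.8235,
    mu_scaled: float = 1.0,
    seed: int | None = None,
    root_sequence: np.ndarray | str | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Finite-sites AT-biased mutations along a genealogy → sequences.

    ``mu_scaled`` is the per-sequence mutation rate per unit branch length
    (default 1.0, matching the genealogy scaling so E[pairwise diffs] ≈ θ up
    to multiple hits).  Substitutions follow the equal-input model with
    AT-biased stationary frequencies (rate i→j ∝ eq_j): each event picks a
    site in proportion to its total exit rate 1−eq(current base) and a new
    base ∝ eq over the other three, so tip composition stays at the target
    equilibrium rather than drifting.  Returns sequences in sample order.
    """
    if mu_scaled < 0:
        raise MitopopError("mu_scaled must be >= 0")
    if not 0 < at_fraction < 1:
        raise MitopopError("at_fraction must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = ts.first()
    if root_sequence is None:
        root = _draw_equilibrium(rng, L, at_fraction)
    elif isinstance(root_sequence, str):
        root = np.frombuffer(root_sequence.encode(), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=int)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        root = lut[root]
    else:
        root = np.asarray(root_sequence, dtype=int)
    if root.shape != (L,):
        raise MitopopError("root_sequence length must equal L")

    eq = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    seqs: dict[int, np.ndarray] = {}
    order = list(tree.nodes(order="preorder"))
    for u in order:
        parent = tree.parent(u)
        base = root if parent == tskit.NULL else seqs[parent]
        seq = base.copy()
        bl = tree.branch_length(u)
        if bl > 0 and mu_scaled > 0:
            m = rng.poisson(bl * mu_scaled)
            for _ in range(m):
                exit_rate = 1.0 - eq[seq]  # equal-input exit rates per site
                site = rng.choice(L, p=exit_rate / exit_rate.sum())
                cur = seq[site]
                w = eq.copy()
                w[cur] = 0.0
                seq[site] = rng.choice(4, p=w / w.sum())
        seqs[u] = seq
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return [lut[seqs[s]].tobytes().decode() for s in ts.samples()]


# ---------------------------------------------------------------------------
# full two-haplogroup dataset


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 6 sites spanning the sampled latitudinal range,
    ~296 sequences of 637 sites, two haplogroups 25 mutations apart with
    opposing clinal frequencies and expansion histories of different ages."""

    site_names: tuple[str, ...] = (
        "North-1", "North-2", "Mid-1", "Mid-2", "Mid-3", "South-1",
    )
    coordinates: tuple[tuple[float, float], ...] = (
        (42.33, -8.88), (38.90, -28.57), (32.63, -16.91),
        (28.10, -16.03), (31.68, -9.85), (16.10, -23.07),
    )
    n_per_site: tuple[int, ...] = (50, 52, 50, 44, 48, 52)
    L: int = 637
    at_fraction: float = 0.8235
    divergence_mutations: int = 25
    #: haplogroup-alpha frequency per site, northernmost first (opposing cline)
    cline: tuple[float, ...] = (0.0, 0.2, 0.5, 0.6, 0.65, 1.0)
    tau_alpha: float = 4.1
    tau_beta: float = 1.2
    theta_alpha: float = 3.7
    theta_beta: float = 1.0
    expansion_ratio: float = 1000.0
    seed: int = 2024

    def __post_init__(self):
        k = len(self.site_names)
        if not (len(self.coordinates) == len(self.n_per_site) == len(self.cline) == k):
            raise MitopopError("per-site config fields must have equal length")
        if any(not 0 <= c <= 1 for c in self.cline):
            raise MitopopError("cline values must lie in [0, 1]")
        if any(n <= 0 for n in self.n_per_site):
            raise MitopopError("sample sizes must be positive")
        if not 0 < self.at_fraction < 1:
            raise MitopopError("at_fraction must be in (0, 1)")


@dataclass
class SimulatedDataset:
    alignment: Alignment
    site_metadata: pd.DataFrame
    truth: dict


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full alignment + metadata + truth record.

    Haplogroup membership per site is Binomial(n_site, cline); the two
    haplogroup founder sequences differ at exactly
    ``divergence_mutations`` sites; each haplogroup's sample coalesces in its
    own sudden-expansion genealogy rooted at its founder.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    founder_a = _draw_equilibrium(rng, cfg.L, cfg.at_fraction)
    founder_b = founder_a.copy()
    div_sites = rng.choice(cfg.L, size=cfg.divergence_mutations, replace=False)
    eq = np.array([cfg.at_fraction / 2, (1 - cfg.at_fraction) / 2,
                   (1 - cfg.at_fraction) / 2, cfg.at_fraction / 2])
    for s in div_sites:
        w = eq.copy()
        w[founder_b[s]] = 0.0
        founder_b[s] = rng.choice(4, p=w / w.sum())

    # per-site haplogroup composition
    n_alpha_site = [int(rng.binomial(n, c)) for n, c in zip(cfg.n_per_site, cfg.cline)]
    n_alpha = sum(n_alpha_site)
    n_beta = sum(cfg.n_per_site) - n_alpha
    if n_alpha < 2 or n_beta < 2:
        raise MitopopError("each haplogroup needs >= 2 sampled specimens; "
                           "adjust cline or sample sizes")

    seqs_by_group = {}
    for label, n_g, tau, theta, founder in (
        ("alpha", n_alpha, cfg.tau_alpha, cfg.theta_alpha, founder_a),
        ("beta", n_beta, cfg.tau_beta, cfg.theta_beta, founder_b),
    ):
        ts = simulate_genealogy(
            n_g, theta, SuddenExpansion(tau, cfg.expansion_ratio),
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        seqs_by_group[label] = apply_mutations(
            ts, cfg.L, cfg.at_fraction, 1.0, root_sequence=founder, rng=rng
        )

    records, labels = [], []
    ia = ib = 0
    spec = 0
    for site, n_site, na in zip(cfg.site_names, cfg.n_per_site, n_alpha_site):
        for j in range(n_site):
            spec += 1
            sid = f"S{spec:04d}"
            if j < na:
                records.append((sid, site, seqs_by_group["alpha"][ia]))
                labels.append("alpha")
                ia += 1
            else:
                records.append((sid, site, seqs_by_group["beta"][ib]))
                labels.append("beta")
                ib += 1
    alignment = make_alignment(records)
    meta = pd.DataFrame(
        {
            "latitude": [c[0] for c in cfg.coordinates],
            "longitude": [c[1] for c in cfg.coordinates],
            "n": list(cfg.n_per_site),
        },
        index=pd.Index(cfg.site_names, name="site"),
    )
    truth = {
        "haplogroup": dict(zip(alignment.specimen_ids, labels)),
        "tau_alpha": cfg.tau_alpha,
        "tau_beta": cfg.tau_beta,
        "theta_alpha": cfg.theta_alpha,
        "theta_beta": cfg.theta_beta,
        "cline": list(cfg.cline),
        "divergence_mutations": cfg.divergence_mutations,
        "n_alpha": n_alpha,
        "n_beta": n_beta,
        "seed": cfg.seed,
    }
    return SimulatedDataset(alignment, meta, truth)


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write FASTA + specimen metadata TSV + truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "alignment.fasta",
        "metadata": out / "specimens.tsv",
        "truth": out / "truth.json",
    }
    coords = {
        site: (row["latitude"], row["longitude"])
        for site, row in dataset.site_metadata.iterrows()
    }
    write_alignment(dataset.alignment, paths["fasta"], paths["metadata"], coords)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    return paths


def simulate_mismatch(
    model: str,
    params,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pairwise-difference histogram for one coalescent sample under an
    expansion model — the parametric-bootstrap engine for mismatch fits.

    ``model="sudden"``: params (tau, theta0, theta1), panmictic with an
    instantaneous size change at mutational time tau.  ``model="spatial"``:
    params (tau, theta, M), the sampled deme belongs to an infinite array of
    demes of size theta exchanging migrants at scaled rate M, all seeded from
    one ancestral deme of size theta at tau.  The full n-sample genealogy is
    built event by event and mutations laid Poisson(branch length) on every
    branch, so the pairwise counts carry the correct genealogical
    correlation.  Branch time runs at per-branch mutation rate 1, making a
    pair's difference count Poisson(2T); the mismatch-model scalings follow:
    pair coalescence hazard 2/θ, per-lineage emigration hazard 2M/θ, epoch
    boundary at t = τ/2.  Returns integer class counts.
    """
    if model == "sudden":
        tau, theta0, theta1 = params
        M = 0.0
        theta_recent, theta_anc = theta1, theta0
    elif model == "spatial":
        tau, theta, M = params
        theta_recent = theta_anc = theta
    else:
        raise MitopopError(f"unknown model {model!r}")
    if n < 2:
        raise MitopopError("n >= 2 required")

    # lineage: (frozenset of sample ids, born_at, in_focal_deme)
    lineages = [(frozenset([i]), 0.0, True) for i in range(n)]
    diffs = np.zeros((n, n))
    all_samples = frozenset(range(n))

    def close_branch(lin, x_now):
        samples, born, _ = lin
        dur = x_now - born
        if dur <= 0:
            return
        m = rng.poisson(dur)
        if m:
            inside = list(samples)
            outside = list(all_samples - samples)
            diffs[np.ix_(inside, outside)] += m
            diffs[np.ix_(outside, inside)] += m

    x = 0.0
    boundary = tau / 2.0  # branch-time units
    epoch_recent = True
    while len(lineages) > 1:
        if epoch_recent:
            k_in = sum(1 for l in lineages if l[2])
            coal_rate = k_in * (k_in - 1) / max(theta_recent, 1e-12)
            mig_rate = k_in * 2.0 * M / max(theta_recent, 1e-12)
        else:
            k_in = len(lineages)
            coal_rate = k_in * (k_in - 1) / max(theta_anc, 1e-12)
            mig_rate = 0.0
        total = coal_rate + mig_rate
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if epoch_recent and x + wait >= boundary:
            # epoch boundary: all lineages drop into the ancestral deme
            x = boundary
            epoch_recent = False
            continue
        x += wait
        focal = [i for i, l in enumerate(lineages) if l[2]] if epoch_recent else list(
            range(len(lineages))
        )
        if rng.random() < coal_rate / total:
            a, b = rng.choice(len(focal), size=2, replace=False)
            ia, ib = focal[a], focal[b]
            la, lb = lineages[ia], lineages[ib]
            close_branch(la, x)
            close_branch(lb, x)
            merged = (la[0] | lb[0], x, True)
            lineages = [l for i, l in enumerate(lineages) if i not in (ia, ib)]
            lineages.append(merged)
        else:
            i = focal[int(rng.integers(len(focal)))]
            s, born, _ = lineages[i]
            lineages[i] = (s, born, False)  # emigrates; alone until epoch end

    counts = diffs[np.triu_indices(n, k=1)].astype(int)
    return np.bincount(counts, minlength=counts.max() + 1 if counts.size else 1)
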