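"""End-to-end report generation.

Two entry points:

* :func:`run_report` — full sequence-level chain on an alignment (read from
  FASTA + metadata, or freshly simulated): per-site diversity/neutrality
  table, pairwise F_ST with permutation P, isolation-by-distance and Mantel,
  median-joining network with haplogroup assignment, per-haplogroup mismatch
  fits, and (given rate inputs) expansion dates.
* :func:`printed_inputs_report` — the differentiation/IBD/dating arithmetic
  recomputed from the published summary tables of the Macaronesian octopus
  survey (:mod:`mitopop.macaronesia`), so the non-sequence parts of the
  chain run without any sequence data.

Every output TSV starts with a comment header carrying the config hash and
seed; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import macaronesia as pub
from .demography import fit_expansion, mismatch_histogram, ssd_bootstrap_p
from .dating import expansion_time, geminate_rate, rate_path
from .errors import MitopopError
from .network import assign_haplogroups, median_joining, write_network
from .popstats import diversity_stats, neutrality_stats
from .seqio import collapse_haplotypes, pairwise_differences, read_alignment
from .simulate import SimulationConfig, simulate_dataset
from .structure import geo_distances, ibd_regression, mean_significant_fst, pairwise_fst

log = logging.getLogger("mitopop")


@dataclass
class AnalysisConfig:
    fasta: str | None = None
    metadata: str | None = None
    simulate: bool = False
    missing_rule: str = "ignore_missing_sites"
    fst_flavor: str = "fst"  # "fst" | "phist"
    n_perm: int = 1000
    n_boot: int = 200
    n_sims: int = 1000
    alpha: float = 0.05
    epsilon: int = 0
    mu_per_site_year: float | None = None
    L: int | None = None
    generation_years: float = pub.GENERATION_YEARS
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: AnalysisConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mitopop config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", **kw)


def run_report(config: AnalysisConfig, out_dir) -> dict:
    """Run the full chain; returns in-memory results and writes the bundle."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if cfg.simulate:
        ds = simulate_dataset(SimulationConfig(seed=cfg.seed))
        alignment, meta = ds.alignment, ds.site_metadata
    else:
        if not (cfg.fasta and cfg.metadata):
            raise MitopopError("fasta and metadata paths required unless simulating")
        alignment, meta = read_alignment(cfg.fasta, cfg.metadata)
    log.info("alignment: %d records x %d sites", alignment.n, alignment.length)

    ht = collapse_haplotypes(alignment, cfg.missing_rule)

    # per-site diversity and neutrality
    rows = []
    for i, site in enumerate(ht.site_labels):
        stats = diversity_stats(ht, alignment, site, cfg.missing_rule)
        neut = neutrality_stats(stats, n_sims=cfg.n_sims, seed=cfg.seed + i)
        rows.append(
            {
                "site": site, "n": stats.n, "k": stats.k,
                "h": round(stats.h, 4), "pi": round(stats.pi, 5),
                "tajima_D": round(neut.tajima_D, 5), "p_D": neut.p_D,
                "fu_Fs": round(neut.fu_Fs, 5), "p_Fs": neut.p_Fs,
            }
        )
    site_stats = pd.DataFrame(rows).set_index("site")
    _write_tsv(site_stats, out / "site_stats.tsv", cfg)

    # differentiation
    hap_dm = pairwise_differences(ht, cfg.missing_rule)
    fst = pairwise_fst(
        ht,
        hap_dm if cfg.fst_flavor == "phist" else None,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    _write_tsv(fst.to_frame().round(5), out / "fst_matrix.tsv", cfg)
    _write_tsv(
        pd.DataFrame(fst.p, index=fst.site_labels, columns=fst.site_labels),
        out / "fst_pvalues.tsv", cfg,
    )

    geo = geo_distances(meta.loc[fst.site_labels])
    ibd = ibd_regression(fst, geo, n_perm=cfg.n_perm, seed=cfg.seed)
    summary = {
        "mean_significant_fst": mean_significant_fst(fst, cfg.alpha),
        "ibd_slope": ibd.slope,
        "ibd_r_squared": ibd.r_squared,
        "ibd_p": ibd.p_value,
        "mantel_Z": ibd.mantel_Z,
        "mantel_r": ibd.mantel_r,
        "mantel_p": ibd.mantel_p,
    }
    _write_tsv(
        pd.DataFrame([summary]).T.rename(columns={0: "value"}),
        out / "ibd_summary.tsv", cfg,
    )

    # network and haplogroups
    net = median_joining(ht, epsilon=cfg.epsilon)
    write_network(net, out / "network_edges.tsv", out / "network.gml")
    groups = assign_haplogroups(net, ht)
    assign = pd.DataFrame(
        {
            "specimen": alignment.specimen_ids,
            "site": alignment.site_labels,
            "haplogroup": groups["specimen_groups"],
        }
    )
    _write_tsv(assign.set_index("specimen"), out / "haplogroups.tsv", cfg)

    # per-haplogroup mismatch fits
    fit_rows = []
    dates = []
    for name in ("alpha", "beta"):
        idx = [i for i, grp in enumerate(groups["specimen_groups"]) if grp == name]
        if len(idx) < 3:
            continue
        sub = alignment.subset(idx)
        mism = mismatch_histogram(pairwise_differences(sub, cfg.missing_rule))
        for model in ("sudden", "spatial"):
            fit = fit_expansion(mism, model)
            fit = ssd_bootstrap_p(fit, mism, n_boot=cfg.n_boot, seed=cfg.seed)
            fit_rows.append(
                {
                    "haplogroup": name, "model": model, "tau": round(fit.tau, 3),
                    "theta0": round(fit.theta0, 3), "theta1": round(fit.theta1, 3),
                    "M": None if fit.M is None else round(fit.M, 3),
                    "SSD": round(fit.SSD, 5), "p_SSD": fit.p_SSD,
                    "raggedness": round(fit.raggedness, 5),
                    "p_raggedness": fit.p_raggedness,
                }
            )
            if cfg.mu_per_site_year:
                date = expansion_time(
                    fit.tau,
                    cfg.mu_per_site_year,
                    cfg.L or alignment.length,
                    cfg.generation_years,
                )
                dates.append(
                    {
                        "haplogroup": name, "model": model, "tau": round(fit.tau, 3),
                        "t_kya": round(date.t_kya, 1),
                    }
                )
    mism_df = pd.DataFrame(fit_rows).set_index(["haplogroup", "model"])
    _write_tsv(mism_df, out / "mismatch_fits.tsv", cfg)
    if dates:
        _write_tsv(
            pd.DataFrame(dates).set_index(["haplogroup", "model"]),
            out / "dating.tsv", cfg,
        )

    log.info("report complete in %.1f s", time.time() - t0)
    return {
        "alignment": alignment,
        "haplotypes": ht,
        "site_stats": site_stats,
        "fst": fst,
        "ibd": ibd,
        "network": net,
        "haplogroups": groups,
        "mismatch_fits": mism_df,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# printed-inputs mode


def published_dating_chain() -> dict:
    """Recompute the rate calibration and the three expansion dates from the
    published inputs (θ ratio, COX1 clock rate, τ per haplogroup/model).

    The transferred control-region rate is rounded to its three printed
    significant figures before dating, matching the precision at which the
    original arithmetic was carried out.
    """
    path = rate_path(
        d_net=pub.GEMINATE_P_DISTANCE,
        T_split_my=pub.ISTHMUS_CLOSURE_MY[0],
        theta_cal=pub.THETA_COX1,
        theta_target=pub.THETA_CR,
        mu_cal_per_site_my=pub.MU_COX1_PER_SITE_MY,
    )
    mu_cr = float(f"{path.mu_target_per_site_year:.3g}")
    dates = {
        ("alpha", "spatial"): expansion_time(
            pub.TAU_ALPHA_SPATIAL, mu_cr, pub.ALIGNMENT_LENGTH, pub.GENERATION_YEARS
        ),
        ("beta", "sudden"): expansion_time(
            pub.TAU_BETA_SUDDEN, mu_cr, pub.ALIGNMENT_LENGTH, pub.GENERATION_YEARS
        ),
        ("beta", "spatial"): expansion_time(
            pub.TAU_BETA_SPATIAL, mu_cr, pub.ALIGNMENT_LENGTH, pub.GENERATION_YEARS
        ),
    }
    geminate = {
        T: geminate_rate(pub.GEMINATE_P_DISTANCE, T) for T in pub.ISTHMUS_CLOSURE_MY
    }
    return {"rate_path": path, "dates": dates, "geminate_rates": geminate}


def published_structure_summary(n_perm: int = 1000, seed: int = 0) -> dict:
    """Mean significant F_ST, IBD regression and Mantel test from the
    published F_ST matrix and site coordinates."""
    from .structure import FstMatrix

    sites, fst, sig = pub.fst_matrix()
    # significance encoded as pseudo-P: 0 for starred pairs, 1 otherwise
    p = np.where(sig, 0.0, 1.0)
    np.fill_diagonal(p, np.nan)
    fm = FstMatrix(sites, fst, p, n_perm=10100, flavor="fst")
    geo = geo_distances(pub.coordinates_frame())
    ibd = ibd_regression(fm, geo, n_perm=n_perm, seed=seed)
    return {
        "mean_significant_fst": mean_significant_fst(fm, alpha=0.05),
        "ibd": ibd,
    }


def printed_inputs_report(out_dir, seed: int = 0) -> dict:
    """Write the printed-inputs bundle (dating + differentiation summaries)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = AnalysisConfig(seed=seed)
    chain = published_dating_chain()
    rows = [
        {
            "haplogroup": hg, "model": model, "tau": d.tau,
            "mu_per_site_year": d.mu_per_site_year, "L": d.L,
            "generation_years": d.generation_years,
            "t_kya": round(d.t_kya, 1),
        }
        for (hg, model), d in chain["dates"].items()
    ]
    _write_tsv(
        pd.DataFrame(rows).set_index(["haplogroup", "model"]),
        out / "dating_published.tsv", cfg,
    )
    summary = published_structure_summary(seed=seed)
    ibd = summary["ibd"]
    _write_tsv(
        pd.DataFrame(
            [
                {
                    "mean_significant_fst": round(summary["mean_significant_fst"], 4),
                    "ibd_r_squared": round(ibd.r_squared, 4),
                    "ibd_p": round(ibd.p_value, 4),
                    "mantel_r": round(ibd.mantel_r, 4),
                    "mantel_p": ibd.mantel_p,
                }
            ]
        ).T.rename(columns={0: "value"}),
        out / "structure_published.tsv", cfg,
    )
    return {"dating": chain, "structure": summary}
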