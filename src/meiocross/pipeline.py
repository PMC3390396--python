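"""End-to-end pipeline: simulate genotypes, run analyses, write a report.

The run configuration is a flat key-value text file (``key = value`` lines,
``#`` comments), e.g.::

    schema_version = 1
    seed = 1
    genotypes = WT,hei10,mer3hei10
    n_cells.WT = 130
    n_cells.hei10 = 130
    n_cells.mer3hei10 = 121
    analyses = gof,ttest,interference,coloc
    coloc_tolerance = 0.01

Every run writes the simulated tables, a per-genotype summary table and a
consolidated plain-text report whose header records the seed, the config
hash and all effective defaults, so a run is self-describing. Outputs are
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chiasma, colocalization, interference, simulate, tables

__all__ = ["RunConfig", "parse_config", "run_pipeline"]

logger = logging.getLogger("meiocross")

SCHEMA_VERSION = 1
KNOWN_ANALYSES = ("gof", "ttest", "interference", "coloc")


@dataclass
class RunConfig:
    seed: int
    genotypes: dict[str, int]  # genotype -> n_cells
    analyses: tuple[str, ...] = KNOWN_ANALYSES
    coloc_tolerance: float = colocalization.DEFAULT_TOLERANCE
    coloc_jitter_sd: float = 0.002
    coloc_dropout_a: float = 0.025
    coloc_dropout_b: float = 0.069
    overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("config must list at least one genotype")
        if not self.analyses:
            raise ValueError("config must enable at least one analysis")
        unknown = set(self.analyses) - set(KNOWN_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")


def parse_config(path) -> RunConfig:
    """Parse a flat key-value config file into a :class:`RunConfig`."""
    text = Path(path).read_text()
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key or not value:
            raise ValueError(f"{path}:{lineno}: empty key or value in {raw!r}")
        pairs[key] = value

    version = int(pairs.pop("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}; this build reads {SCHEMA_VERSION}")
    if "seed" not in pairs:
        raise ValueError("config must set 'seed'")
    seed = int(pairs.pop("seed"))
    genotype_names = [g.strip() for g in pairs.pop("genotypes", "WT,hei10").split(",")]
    analyses = tuple(a.strip() for a in pairs.pop("analyses", ",".join(KNOWN_ANALYSES)).split(","))

    genotypes: dict[str, int] = {}
    overrides: dict[str, dict[str, float]] = {}
    kwargs: dict[str, float] = {}
    for key, value in pairs.items():
        if key.startswith("n_cells."):
            genotypes[key.removeprefix("n_cells.")] = int(value)
        elif key.startswith("genotype."):
            _, geno, param = key.split(".", 2)
            overrides.setdefault(geno, {})[param] = float(value)
        elif key in ("coloc_tolerance", "coloc_jitter_sd", "coloc_dropout_a", "coloc_dropout_b"):
            kwargs[key] = float(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    for name in genotype_names:
        genotypes.setdefault(name, 100)
    genotypes = {g: genotypes[g] for g in genotype_names}

    return RunConfig(
        seed=seed,
        genotypes=genotypes,
        analyses=analyses,
        overrides=overrides,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
        **kwargs,
    )


def _derived_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Simulate every genotype, run the enabled analyses, write the report.

    Returns the results as a nested dict (the report file renders the same
    numbers; nothing is re-rounded between the two).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run: seed=%d config_hash=%s genotypes=%s", config.seed, config.config_hash,
                ",".join(config.genotypes))

    results: dict = {"seed": config.seed, "config_hash": config.config_hash, "genotypes": {}}
    datasets: dict[str, tuple[pd.DataFrame, pd.DataFrame, simulate.SimConfig]] = {}
    for i, (genotype, n_cells) in enumerate(config.genotypes.items()):
        sim_cfg = simulate.genotype_config(
            genotype, n_cells=n_cells, seed=_derived_seed(config.seed, i),
            **config.overrides.get(genotype, {}),
        )
        cells, foci = simulate.simulate_dataset(sim_cfg)
        simulate.write_tables(cells, foci, out / f"cells_{genotype}.tsv", out / f"foci_{genotype}.tsv")
        datasets[genotype] = (cells, foci, sim_cfg)
        logger.info("simulated %s: %d cells", genotype, n_cells)

    summary_rows = []
    for genotype, (cells, _, _) in datasets.items():
        per_cell = chiasma.cell_summaries_from_table(cells)
        mean, sd, n = chiasma.summarize_genotype(per_cell["chiasma_count"])
        block = {"n": n, "mean": mean, "sd": sd,
                 "mean_bivalents": float(per_cell["bivalent_count"].mean())}
        if "gof" in config.analyses:
            gof = chiasma.poisson_gof(per_cell["chiasma_count"].tolist())
            block["gof"] = {"chi2": gof.chi2, "df": gof.df, "p_value": gof.p_value,
                            "lambda_hat": gof.lambda_hat}
        results["genotypes"][genotype] = block
        summary_rows.append({"genotype": genotype, **{k: v for k, v in block.items() if k != "gof"},
                             **{f"gof_{k}": v for k, v in block.get("gof", {}).items()}})
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)

    if "ttest" in config.analyses and len(datasets) >= 2:
        results["ttests"] = {}
        names = list(datasets)
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                b1, b2 = results["genotypes"][g1], results["genotypes"][g2]
                tt = chiasma.pooled_t_test(b1["mean"], b1["sd"], b1["n"], b2["mean"], b2["sd"], b2["n"])
                results["ttests"][f"{g1}_vs_{g2}"] = {"t": tt.t, "df": tt.df, "p_value": tt.p_value}

    if "interference" in config.analyses:
        results["interference"] = {}
        for genotype, (cells, foci, sim_cfg) in datasets.items():
            if sim_cfg.class1_mu == 0:
                continue
            shortest = int(np.argmin(sim_cfg.sc_lengths))
            bright = foci[(foci["channel"] == simulate.BRIGHT_CHANNEL)
                          & (foci["bivalent_id"] == shortest)]
            dset = interference.interfocus_distances(bright)
            if dset.n < 3:
                logger.warning("%s: too few inter-focus distances (%d); skipping fit", genotype, dset.n)
                continue
            mle = interference.fit_gamma_mle(dset)
            block = {"chromosome": shortest, "n_gaps": dset.n,
                     "mle": {"nu_hat": mle.nu_hat, "se_nu": mle.se_nu,
                             "scale_hat": mle.scale_hat, "loglik": mle.loglik},
                     "mom_nu": interference.mom_shape(dset)}
            if dset.n >= 20:
                binned = interference.fit_gamma_binned(dset)
                block["binned"] = {"nu_hat": binned.nu_hat, "scale_hat": binned.scale_hat}
            results["interference"][genotype] = block

    if "coloc" in config.analyses:
        results["coloc"] = {}
        rng = np.random.default_rng(_derived_seed(config.seed, 10_001))
        for genotype, (cells, foci, sim_cfg) in datasets.items():
            bright = foci[foci["channel"] == simulate.BRIGHT_CHANNEL]
            if bright.empty:
                continue
            rows_a, rows_b = [], []
            for (cid, biv), grp in bright.groupby(["cell_id", "bivalent_id"], sort=True):
                ch_a, ch_b = simulate.simulate_dual_channel(
                    grp["position_frac"].to_numpy(),
                    jitter_sd=config.coloc_jitter_sd,
                    dropout_a=config.coloc_dropout_a,
                    dropout_b=config.coloc_dropout_b,
                    rng=rng,
                )
                rows_a += [(cid, biv, "A", p) for p in ch_a]
                rows_b += [(cid, biv, "B", p) for p in ch_b]
            if not rows_a or not rows_b:
                continue
            cols = ["cell_id", "bivalent_id", "channel", "position_frac"]
            res = colocalization.coloc_fractions(
                pd.DataFrame(rows_a, columns=cols), pd.DataFrame(rows_b, columns=cols),
                tolerance=config.coloc_tolerance,
            )
            results["coloc"][genotype] = {
                "fraction_a_with_b": res.fraction_a_with_b,
                "fraction_b_with_a": res.fraction_b_with_a,
                "tolerance": res.tolerance, "n_a": res.n_a, "n_b": res.n_b,
            }

    (out / "report.txt").write_text(render_report(config, results))
    logger.info("report written to %s", out / "report.txt")
    return results


def render_report(config: RunConfig, results: dict) -> str:
    """Render the consolidated plain-text report.

    Numbers are printed at full precision with a rounded display column in
    the cytogenetics convention (mean +/- SD, one decimal).
    """
    lines = [
        "# meiocross consolidated report",
        f"# seed = {config.seed}",
        f"# config_hash = {config.config_hash}",
        f"# analyses = {','.join(config.analyses)}",
        f"# coloc_tolerance = {config.coloc_tolerance} (fraction of SC length)",
        "",
        "## Chiasma frequency per genotype",
        "genotype\tn\tmean\tsd\tdisplay",
    ]
    for genotype, block in results["genotypes"].items():
        lines.append(
            f"{genotype}\t{block['n']}\t{block['mean']!r}\t{block['sd']!r}"
            f"\t{block['mean']:.1f}+/-{block['sd']:.1f}"
        )
    gofs = {g: b["gof"] for g, b in results["genotypes"].items() if "gof" in b}
    if gofs:
        lines += ["", "## Poisson goodness of fit (per-cell chiasma counts)",
                  "genotype\tchi2\tdf\tp_value"]
        for genotype, gof in gofs.items():
            lines.append(f"{genotype}\t{gof['chi2']!r}\t{gof['df']}\t{gof['p_value']!r}")
    if "ttests" in results:
        lines += ["", "## Pairwise pooled t-tests", "pair\tt\tdf\tp_value\tdisplay"]
        for pair, tt in results["ttests"].items():
            lines.append(f"{pair}\t{tt['t']!r}\t{tt['df']}\t{tt['p_value']!r}"
                         f"\tt[{tt['df']}]={tt['t']:.1f}")
    if results.get("interference"):
        lines += ["", "## Gamma interference fit (shortest chromosome, bright foci)",
                  "genotype\tmethod\tnu_hat\tse_nu\tscale_hat\tn_gaps\tdisplay"]
        for genotype, block in results["interference"].items():
            mle = block["mle"]
            lines.append(f"{genotype}\tmle\t{mle['nu_hat']!r}\t{mle['se_nu']!r}"
                         f"\t{mle['scale_hat']!r}\t{block['n_gaps']}"
                         f"\tnu={mle['nu_hat']:.2f} (SE {mle['se_nu']:.2f})")
            lines.append(f"{genotype}\tmom\t{block['mom_nu']!r}\t\t\t{block['n_gaps']}"
                         f"\tnu={block['mom_nu']:.2f}")
            if "binned" in block:
                lines.append(f"{genotype}\tbinned_ls\t{block['binned']['nu_hat']!r}\t"
                             f"\t{block['binned']['scale_hat']!r}\t{block['n_gaps']}"
                             f"\tnu={block['binned']['nu_hat']:.2f}")
    if results.get("coloc"):
        lines += ["", "## Dual-channel colocalization (threshold matching)",
                  "genotype\tfrac_A_with_B\tfrac_B_with_A\ttolerance\tn_A\tn_B\tdisplay"]
        for genotype, c in results["coloc"].items():
            lines.append(
                f"{genotype}\t{c['fraction_a_with_b']!r}\t{c['fraction_b_with_a']!r}"
                f"\t{c['tolerance']}\t{c['n_a']}\t{c['n_b']}"
                f"\t{100 * c['fraction_a_with_b']:.1f}%/{100 * c['fraction_b_with_a']:.1f}%"
            )
    lines.append("")
    return "\n".join(lines)
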