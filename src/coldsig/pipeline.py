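"""End-to-end orchestration: demo-bundle generation and the run-all driver.

``make_demo`` produces a complete synthetic input bundle shaped like a
nine-pool walnut cold-hardiness study: a VCF/BED variant panel (33
candidate cold-hardy genes + random background genes), electrolyte-leakage
conductivity tables at -10/-20/-30 C, qPCR Ct tables at 4/-10/-20/-30/-38 C,
and nuclear + organellar FASTA sets for 12 taxa in three continent-like
clades, with one butternut-like taxon whose nuclear sequences derive from
the East-Asian clade but whose organellar sequences derive from the
North-American clade (a built-in nuclear/organellar discordance).

``run_all`` executes every analysis stage on such a bundle and writes a
deterministic set of CSV/Newick outputs plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import expression, panelio, phylo, physiology, popgen, simulate, sweep

logger = logging.getLogger("coldsig")

#: the nine demo pools and their diploid sample sizes (species counts of a
#: 38-genome panel; the single J. hindsii accession forms a one-sample pool)
DEMO_POOLS = {
    "JW": 5,  # Japanese walnut, J. ailantifolia
    "BW": 6,  # black walnut, J. nigra
    "BN": 5,  # butternut, J. cinerea
    "HY": 4,  # interspecific F1 hybrids + BC1
    "AW": 3,  # Arizona walnut, J. major
    "MW": 5,  # Manchurian walnut, J. mandshurica
    "PWA": 4,  # Persian walnut, Asia
    "PWU": 7,  # Persian walnut, United States
    "NCB": 1,  # northern California black walnut, J. hindsii
}

#: pools whose candidate genes carry a sweep-like footprint in the demo
DEMO_SWEEP_POOLS = ("PWA", "PWU")
#: pool whose candidate genes carry the hybrid / balancing footprint
DEMO_BALANCING_POOLS = ("HY",)

DEMO_SPECIES = {
    "JW": "J. ailantifolia",
    "BW": "J. nigra",
    "BN": "J. cinerea",
    "HY": "F1 hybrid",
    "AW": "J. major",
    "MW": "J. mandshurica",
    "PWA": "J. regia (Asia)",
    "PWU": "J. regia (US)",
    "NCB": "J. hindsii",
}

EL_TEMPERATURES = (-10.0, -20.0, -30.0)
QPCR_CONDITIONS = (4.0, -10.0, -20.0, -30.0, -38.0)


@dataclass
class RunConfig:
    """Single-file configuration for a full pipeline run."""

    out_dir: str
    vcf: str = ""
    bed: str = ""
    el_csv: str = ""
    ct_csv: str = ""
    fasta_dirs: Mapping[str, str] = field(default_factory=dict)  # tree name -> dir
    matrix_csvs: Mapping[str, str] = field(default_factory=dict)  # tree name -> csv
    pool_samples: Mapping[str, Sequence[str]] = field(default_factory=dict)
    keywords: Sequence[str] = sweep.DEFAULT_KEYWORDS
    max_missing: float = 0.5
    d_threshold: float = -0.5
    percentile_threshold: float = 7.5
    alpha: float = 0.05
    kmer_k: int = 25
    control_condition: float = 4.0
    seed: int = 0
    focal_taxon: str = ""
    focal_group: Mapping[str, Sequence[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# demo bundle


def demo_sim_config(
    seed: int,
    n_candidate: int = 33,
    n_random: int = 200,
    theta: float = 5.0,
    gene_length: int = 1500,
    sweep_scale: float = 0.1,
    balancing_boost: float = 5.0,
) -> simulate.SimConfig:
    pools = [simulate.PoolSpec(name, n) for name, n in DEMO_POOLS.items()]
    genes = []
    regimes = {p: "sweep" for p in DEMO_SWEEP_POOLS}
    regimes.update({p: "balancing" for p in DEMO_BALANCING_POOLS})
    for i in range(n_candidate):
        genes.append(
            simulate.GeneSpec(
                gene_id=f"g{1000 + i}",
                length=gene_length,
                gene_class="candidate",
                label=simulate.CANDIDATE_LABELS[i % len(simulate.CANDIDATE_LABELS)],
                regimes=dict(regimes),
            )
        )
    for i in range(n_random):
        genes.append(
            simulate.GeneSpec(
                gene_id=f"r{5000 + i}",
                length=gene_length,
                gene_class="random",
                label=simulate.BACKGROUND_LABELS[i % len(simulate.BACKGROUND_LABELS)],
            )
        )
    return simulate.SimConfig(
        seed=seed,
        pools=pools,
        genes=genes,
        theta=theta,
        sweep_scale=sweep_scale,
        balancing_boost=balancing_boost,
    )


def _demo_el_truth() -> pd.DataFrame:
    """Known damage indices: hardy species leak little, tender species a lot."""
    base = {  # DI at -10, -20, -30
        "BN": (5, 12, 20),
        "BW": (6, 14, 22),
        "JW": (8, 20, 35),
        "MW": (8, 22, 38),
        "HY": (10, 25, 45),
        "PWU": (15, 40, 70),
        "AW": (18, 45, 75),
        "NCB": (20, 48, 80),
        "PWA": (20, 50, 85),
    }
    rows = []
    for pool, dis in base.items():
        for temp, di in zip(EL_TEMPERATURES, dis):
            # three genotypes per species so species-level ANOVA has
            # within-group replication
            for g, offset in enumerate((-3.0, 0.0, 3.0), start=1):
                rows.append(
                    {
                        "genotype": f"{pool}_g{g}",
                        "species": DEMO_SPECIES[pool],
                        "temperature": temp,
                        "di": float(np.clip(di + offset, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)


def _demo_ct_truth() -> pd.DataFrame:
    """Known fold changes: hardy species keep induction at deep frost."""
    profile = {  # fold at -10, -20, -30, -38 relative to 4 C control
        "BN": (6, 9, 10, 8),
        "BW": (5, 8, 9, 7),
        "JW": (4, 5, 4, 3),
        "MW": (4, 5, 4, 3),
        "HY": (4, 5, 3, 2),
        "PWU": (3, 3, 0.8, 0.4),
        "PWA": (2.5, 2.5, 0.6, 0.3),
        "AW": (2, 2, 0.5, 0.3),
        "NCB": (2, 2, 0.5, 0.3),
    }
    rows = []
    for pool, folds in profile.items():
        for cond, fold in zip(QPCR_CONDITIONS[1:], folds):
            rows.append(
                {
                    "sample": pool,
                    "species": DEMO_SPECIES[pool],
                    "condition": cond,
                    "fold": float(fold),
                }
            )
    return pd.DataFrame(rows)


#: demo taxa in three continent-like clades; "BN_like" is the discordant
#: butternut-like taxon (nuclear: East Asia; organellar: North America)
DEMO_CLADES = {
    "north_america": ["BW", "NCB", "AW", "RoyalF1"],
    "east_asia": ["JW", "MW", "Buart"],
    "europe": ["PW1", "PW2", "PW3", "Carpathian"],
}
DEMO_FOCAL = "BN_like"


def _demo_taxon_tree(clades: Mapping[str, Sequence[str]], focal_in: str, prob: float):
    """Balanced 3-clade tree with the focal taxon inside ``focal_in``."""

    def leaf(name):
        return phylo.Clade(name=name, branch_length=prob)

    clade_nodes = []
    for cname, members in clades.items():
        leaves = [leaf(m) for m in members]
        if cname == focal_in:
            leaves.append(leaf(DEMO_FOCAL))
        node = phylo.Clade(branch_length=2 * prob, children=leaves)
        clade_nodes.append(node)
    return phylo.Clade(branch_length=0.0, children=clade_nodes)


def make_demo(
    out_dir: str,
    seed: int = 0,
    n_candidate: int = 33,
    n_random: int = 200,
    seq_length: int = 40_000,
    seq_prob: float = 0.01,
    theta: float = 5.0,
) -> RunConfig:
    """Write a complete synthetic input bundle and return its RunConfig."""
    os.makedirs(out_dir, exist_ok=True)
    root = np.random.SeedSequence(seed)
    ss_panel, ss_el, ss_ct, ss_nuc, ss_org = root.spawn(5)

    sim_cfg = demo_sim_config(
        seed=int(ss_panel.generate_state(1)[0] % 2**31), n_candidate=n_candidate,
        n_random=n_random, theta=theta,
    )
    vcf_path = os.path.join(out_dir, "panel.vcf")
    bed_path = os.path.join(out_dir, "genes.bed")
    simulate.emit_panel(sim_cfg, vcf_path, bed_path)

    el_path = os.path.join(out_dir, "el_trials.csv")
    simulate.simulate_el_table(
        _demo_el_truth(), el_noise_sd=0.01, seed=ss_el, replicates=3
    ).to_csv(el_path, index=False)

    ct_path = os.path.join(out_dir, "ct_records.csv")
    simulate.simulate_ct_table(
        _demo_ct_truth(), ct_noise_sd=0.2, replicates=(3, 3), seed=ss_ct
    ).to_csv(ct_path, index=False)

    fasta_dirs = {}
    for tree_name, focal_in, ss in (
        ("nuclear", "east_asia", ss_nuc),
        ("organellar", "north_america", ss_org),
    ):
        tree = _demo_taxon_tree(DEMO_CLADES, focal_in, seq_prob)
        seqs = simulate.evolve_sequences(tree, seq_length, np.random.default_rng(ss))
        d = os.path.join(out_dir, f"fasta_{tree_name}")
        os.makedirs(d, exist_ok=True)
        for name, seq in seqs.items():
            simulate.write_fasta({name: seq}, os.path.join(d, f"{name}.fasta"))
        fasta_dirs[tree_name] = d

    cfg = RunConfig(
        out_dir=os.path.join(out_dir, "results"),
        vcf=vcf_path,
        bed=bed_path,
        el_csv=el_path,
        ct_csv=ct_path,
        fasta_dirs=fasta_dirs,
        pool_samples={
            p.name: [f"{p.name}_{i + 1}" for i in range(p.n_diploids)]
            for p in sim_cfg.pools
        },
        seed=seed,
        focal_taxon=DEMO_FOCAL,
        focal_group={
            "nuclear": list(DEMO_CLADES["east_asia"]),
            "organellar": list(DEMO_CLADES["north_america"]),
        },
    )
    cfg.to_yaml(os.path.join(out_dir, "run_config.yaml"))
    return cfg


# ---------------------------------------------------------------------------
# stages


def stats_from_files(
    vcf: str,
    bed: str,
    pool_samples: Mapping[str, Sequence[str]],
    max_missing: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene-per-pool statistics table + per-gene F_ST from VCF/BED."""
    intervals = panelio.read_bed(bed)
    pools = panelio.read_vcf_pools(vcf, pool_samples)
    pools_by_gene = {
        iv.gene_id: [panelio.pool_view(p, iv) for p in pools.values()]
        for iv in intervals
    }
    return popgen.stats_table(pools_by_gene, intervals)


def run_all(config: RunConfig) -> dict:
    """Run every stage for which inputs are present; return the manifest.

    Stages with missing inputs are skipped with a logged notice; any stage
    failure is re-raised with the stage name attached.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"stages": {}, "row_counts": {}}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # pragma: no cover - error path
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = "ok"
        return result

    stats_df = None
    if config.vcf and config.bed:
        def _popgen():
            stats, fst = stats_from_files(
                config.vcf, config.bed, config.pool_samples, config.max_missing
            )
            popgen.serialize_stats(stats).to_csv(out("gene_stats.csv"), index=False)
            fst.to_csv(out("gene_fst.csv"), index=False)
            manifest["row_counts"]["gene_stats"] = len(stats)
            manifest["row_counts"]["gene_fst"] = len(fst)
            return stats

        stats_df = stage("popgen", _popgen)

        def _sweep():
            calls = sweep.call_sweeps(
                stats_df, config.d_threshold, config.percentile_threshold
            )
            summary, contrast = sweep.summarize_pools(stats_df, calls, config.alpha)
            calls.to_csv(out("sweep_calls.csv"), index=False)
            summary.to_csv(out("pool_summary.csv"), index=False)
            contrast.to_csv(out("candidate_contrast.csv"), index=False)
            manifest["row_counts"]["sweep_calls"] = len(calls)
            return calls

        stage("sweep_screen", _sweep)
    else:
        logger.info("variant panel missing; popgen + sweep stages skipped")

    if config.el_csv:
        def _phys():
            trials = pd.read_csv(config.el_csv)
            di = physiology.damage_index_table(trials)
            di.to_csv(out("damage_index.csv"), index=False)
            summ = physiology.group_summary(di, "di", keys=("species", "temperature"))
            summ.to_csv(out("damage_index_summary.csv"), index=False)
            letters_rows = []
            for temp, cell in di.groupby("temperature", sort=False):
                res = physiology.anova_lsd(cell["di"], cell["species"], config.alpha)
                for g, letter in res.letters.items():
                    letters_rows.append(
                        {
                            "temperature": temp,
                            "species": g,
                            "mean_di": res.group_means[g],
                            "letters": letter,
                            "anova_f": res.f_statistic,
                            "anova_p": res.p_value,
                        }
                    )
            pd.DataFrame(letters_rows).to_csv(out("damage_index_lsd.csv"), index=False)
            manifest["row_counts"]["damage_index"] = len(di)

        stage("physiology", _phys)
    else:
        logger.info("EL table missing; physiology stage skipped")

    if config.ct_csv:
        def _expr():
            ct = pd.read_csv(config.ct_csv)
            prof = expression.expression_profile(ct, config.control_condition)
            prof.to_csv(out("fold_change.csv"), index=False)
            manifest["row_counts"]["fold_change"] = len(prof)

        stage("expression", _expr)
    else:
        logger.info("Ct table missing; expression stage skipped")

    clade_rows = []
    for tree_name, src in list(config.fasta_dirs.items()):
        def _phylo(tree_name=tree_name, src=src):
            profiles = []
            for fn in sorted(os.listdir(src)):
                if not fn.endswith((".fasta", ".fa")):
                    continue
                label = os.path.splitext(fn)[0]
                profiles.append(
                    phylo.kmer_profile_from_fasta(
                        os.path.join(src, fn), k=config.kmer_k, label=label
                    )
                )
            dm = phylo.DistanceMatrix.from_profiles(profiles)
            tree = phylo.neighbor_joining(dm)
            tree.write(out(f"tree_{tree_name}.nwk"))
            if config.focal_taxon:
                group = config.focal_group.get(tree_name, [])
                if group:
                    clade_rows.append(
                        {
                            "tree": tree_name,
                            "focal": config.focal_taxon,
                            "group": ";".join(group),
                            "monophyletic_with_group": phylo.clade_check(
                                tree, config.focal_taxon, group
                            ),
                        }
                    )

        stage(f"phylo_{tree_name}", _phylo)
    for tree_name, src in list(config.matrix_csvs.items()):
        def _phylo_m(tree_name=tree_name, src=src):
            dm = phylo.DistanceMatrix.read_csv(src)
            tree = phylo.neighbor_joining(dm)
            tree.write(out(f"tree_{tree_name}.nwk"))

        stage(f"phylo_{tree_name}", _phylo_m)
    if clade_rows:
        pd.DataFrame(clade_rows).to_csv(out("clade_checks.csv"), index=False)

    cfg_json = json.dumps(_plain(asdict(config)), sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    from . import __version__

    manifest["coldsig_version"] = __version__
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
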