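"""Full-analysis pipeline: diversity -> structure -> gene flow -> demography.

One configuration drives every stage and a single root seed feeds
deterministic per-stage substreams, so a rerun with the same config is
byte-identical.  Each table is written as a tab-separated file (4-decimal
rounding for report tables) and every number also lands, at full precision,
in a machine-readable ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .demography import neutrality_tests
from .differentiation import amova, gst_nst, pairwise_phist
from .diversity import population_diversity_table, summarize_populations
from .errors import ConfigError, PopgenflowError
from .geneflow import gene_flow_from_fst, jackknife, per_locus_sd
from .io import (
    AlignedSequenceSet,
    call_haplotypes,
    pairwise_differences,
    read_alignment,
    read_metadata,
    read_popmap,
    segregating_sites,
)
from .network import build_network
from .spatial import covariate_matrix, haversine_matrix, ibd_regression, mantel_test

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run; load from YAML with :meth:`from_yaml`."""

    biparental_fasta: str
    popmap: str
    outdir: str
    seed: int
    maternal_fasta: str | None = None
    metadata: str | None = None
    n_perm: int = 999
    n_boot: int = 0
    gap_policy: str = "complete"
    run_ibd: bool = True
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        missing = {"biparental_fasta", "popmap", "outdir", "seed"} - set(kwargs)
        if missing:
            raise ConfigError(f"config missing required fields: {sorted(missing)}")
        return cls(extra=extra, **kwargs)

    def validate(self) -> None:
        for label, p in (("biparental_fasta", self.biparental_fasta),
                         ("popmap", self.popmap),
                         ("maternal_fasta", self.maternal_fasta),
                         ("metadata", self.metadata)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config field {label}: path {p!r} does not exist")
        if self.run_ibd and self.metadata is None:
            raise ConfigError("IBD stage enabled but config field 'metadata' is missing")
        if self.seed is None:
            raise ConfigError("a root seed is required")


def _round_table(df, ndigits=4):
    return df.round(ndigits)


def _stage_seeds(root: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(root)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("popgenflow").addHandler(handler)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "n_perm": cfg.n_perm, "gap_policy": cfg.gap_policy}
    seeds = _stage_seeds(cfg.seed, ["amova_bip", "amova_mat", "pairwise", "gstnst",
                                    "ibd", "mantel", "perlocus"])
    stage = "load"
    try:
        popmap = read_popmap(cfg.popmap)
        bip = read_alignment(cfg.biparental_fasta, popmap, "biparental")
        mat = (read_alignment(cfg.maternal_fasta, popmap, "maternal")
               if cfg.maternal_fasta else None)

        stage = "diversity"
        summary["diversity"] = {}
        for aln in filter(None, [bip, mat]):
            table = population_diversity_table(aln, cfg.gap_policy)
            _round_table(table.set_index("population")).to_csv(
                outdir / f"diversity_{aln.marker_name}.tsv", sep="\t")
            block = {"per_population": table.set_index("population").to_dict("index")}
            for stat in ("pi", "theta_w", "h"):
                s = summarize_populations(table[stat], stat)
                block[f"{stat}_mean"] = s.mean
                block[f"{stat}_sd"] = s.sd
            summary["diversity"][aln.marker_name] = block

        stage = "differentiation"
        summary["differentiation"] = {}
        fst_bip = None
        for aln, skey in [(bip, "amova_bip"), (mat, "amova_mat")]:
            if aln is None:
                continue
            d = pairwise_differences(aln, cfg.gap_policy)
            res = amova(d, n_perm=cfg.n_perm, seed=seeds[skey])
            _round_table(res.as_table()).to_csv(
                outdir / f"amova_{aln.marker_name}.tsv", sep="\t", index=False)
            summary["differentiation"][aln.marker_name] = {
                "phi_st": res.phi_st, "p_value": res.p_value,
                "pct_among": res.pct_among, "pct_within": res.pct_within,
                "sigma2_among": res.sigma2_among, "sigma2_within": res.sigma2_within,
            }
            if aln is bip:
                fst_bip = pairwise_phist(d, n_perm=0, seed=seeds["pairwise"])
                _round_table(fst_bip.as_frame()).to_csv(
                    outdir / "pairwise_phist_biparental.tsv", sep="\t")

        stage = "gst_nst"
        target = mat if mat is not None else bip
        hap = call_haplotypes(target, cfg.gap_policy)
        if hap.n_haplotypes > 1:
            gn = gst_nst(hap, n_perm=cfg.n_perm, seed=seeds["gstnst"])
            summary["gst_nst"] = {k: getattr(gn, k) for k in
                                  ("hS", "hT", "vS", "vT", "Gst", "Nst", "p_nst_gt_gst")}

        stage = "network"
        net = build_network(hap, keep_alternate_minimal_edges=True)
        net.edge_table().to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        net.node_table().to_csv(outdir / "network_nodes.tsv", sep="\t", index=False)
        summary["network"] = {"n_haplotypes": hap.n_haplotypes,
                              "n_edges": net.graph.number_of_edges(),
                              "is_tree": net.is_tree}

        if cfg.run_ibd and cfg.metadata:
            stage = "spatial"
            meta = read_metadata(cfg.metadata)
            order = [m.code for m in meta]
            if fst_bip is not None and set(order) == set(fst_bip.codes):
                reorder = [fst_bip.codes.index(c) for c in order]
                fvals = fst_bip.values[np.ix_(reorder, reorder)]
                geo = haversine_matrix(meta)
                ibd = ibd_regression(fvals, geo.values, n_perm=cfg.n_perm,
                                     seed=seeds["ibd"])
                summary["ibd"] = {k: getattr(ibd, k) for k in
                                  ("intercept", "slope", "r_squared", "p_slope",
                                   "pearson_r", "p_pearson", "n_pairs", "excluded_pairs")}
                summary["mantel"] = {}
                for name in ("geographic_km", "elevation_m", "aap_mm", "aat_c"):
                    cov = covariate_matrix(meta, name)
                    mres = mantel_test(cov.values, fvals, n_perm=cfg.n_perm,
                                       seed=seeds["mantel"])
                    summary["mantel"][name] = {"r": mres.r, "p_upper": mres.p_upper,
                                               "p_lower": mres.p_lower}

        stage = "geneflow"
        if mat is not None:
            dmat = pairwise_differences(mat, cfg.gap_policy)
            positions = segregating_sites(mat, cfg.gap_policy)
            per_locus = []
            for pos in positions:
                col = mat.matrix[:, pos - 1]
                dcol = (col[:, None] != col[None, :]).astype(float)
                per_locus.append(amova(dcol, mat.pop_labels, n_perm=0).phi_st)
            if len(per_locus) >= 2:
                fstm, sd_fstm = per_locus_sd(per_locus)
            else:
                fstm = amova(dmat, n_perm=0).phi_st
                sd_fstm = 0.0
            dbip = pairwise_differences(bip, cfg.gap_policy)
            pops = bip.populations()

            def drop_pop(i):
                keep = np.flatnonzero(dbip.populations != pops[i])
                return amova(dbip.d[np.ix_(keep, keep)],
                             dbip.populations[keep], n_perm=0).phi_st

            fstn, _, sd_fstn = jackknife(drop_pop, pops)
            fstn_full = amova(dbip, n_perm=0).phi_st
            gf = gene_flow_from_fst(fstn_full, fstm, sd_fstn, sd_fstm)
            summary["gene_flow"] = gf.as_dict() | {
                "per_locus_phist_maternal": per_locus,
                "fstn_jackknife_mean": fstn,
            }

        stage = "neutrality"
        table = []
        for pop, sub in bip.by_population().items():
            S = len(segregating_sites(sub, cfg.gap_policy))
            if S < 1 or sub.n < 4:
                table.append({"population": pop, "tajima_d": None,
                              "p_tajima": None, "fu_fs": None})
                continue
            d = pairwise_differences(sub, cfg.gap_policy)
            k_hat = float(np.triu(d.d, 1).sum()) / (sub.n * (sub.n - 1) / 2)
            k_obs = call_haplotypes(sub, cfg.gap_policy).n_haplotypes
            res = neutrality_tests(pop, S, sub.n, k_hat, k_obs)
            table.append({"population": pop, "tajima_d": res.tajima_d,
                          "p_tajima": res.p_tajima, "fu_fs": res.fu_fs})
        summary["neutrality"] = {row["population"]: row for row in table}
        import pandas as pd
        _round_table(pd.DataFrame(table).set_index("population")).to_csv(
            outdir / "neutrality_biparental.tsv", sep="\t")

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        logger.info("pipeline complete: %s", outdir)
        return summary
    except PopgenflowError as exc:
        raise PopgenflowError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("popgenflow").removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
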