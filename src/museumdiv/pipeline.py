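"""End-to-end orchestration: ultrametricize -> delimit -> reduce -> dec -> divtest.

Each stage is a thin wrapper over the library modules that reads/writes
plain-text artifacts (newick, TSV, JSON, FASTA) under a run directory and
contributes a section to a combined JSON report.  The externally dated
chronogram is a pass-through input between the reduction and
biogeography stages: Bayesian relaxed-clock dating is done by external
tools and is deliberately not re-implemented here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dec import StratifiedDispersalModel, build_state_space, dec_optimize
from .divrate import (EVENT_TIMES_MA, delta_aic_rc, fit_all_models, gamma_stat,
                      mccr_test, ms_netdiv, rel_cladogenesis_test,
                      shift_at_time_test)
from .gmyc import consensus_reduce, gmyc_fit
from .mpl import mpl_ultrametricize
from .phylo import (TreeError, as_chronogram, branching_times, extract_clade,
                    ltt_table, prune_tips, read_tree, write_newick)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_model_config",
    "read_ranges_tsv",
    "write_ranges_tsv",
    "read_fasta",
    "write_fasta",
    "divtest_report",
]


# ---------------------------------------------------------------------------
# I/O helpers


def load_model_config(path: str | Path) -> dict:
    """Load a DEC model config (YAML or JSON) mirroring the deposited format.

    Keys: areas, boundaries, matrices (one per slice, oldest first),
    excluded (optional range strings like "AF"), root_range (optional),
    maxareas (optional, default 2).
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    required = {"areas", "boundaries", "matrices"}
    missing = required - set(cfg)
    if missing:
        raise ValueError(f"DEC model config missing keys: {sorted(missing)}")
    return cfg


def model_from_config(cfg: dict, d: float = 0.0, e: float = 0.0):
    model = StratifiedDispersalModel(
        areas=tuple(cfg["areas"]),
        boundaries=tuple(cfg["boundaries"]),
        matrices=tuple(np.asarray(m, dtype=float) for m in cfg["matrices"]),
        d=d, e=e,
    )
    space = build_state_space(
        list(cfg["areas"]),
        maxareas=int(cfg.get("maxareas", 2)),
        excluded=[list(x) for x in cfg.get("excluded", [])],
    )
    root_range = frozenset(cfg["root_range"]) if cfg.get("root_range") else None
    return model, space, root_range


def read_ranges_tsv(path: str | Path, areas: list[str]) -> dict[str, frozenset]:
    """Tip ranges from TSV: tip_id column plus one 0/1 column per area."""
    df = pd.read_csv(path, sep="\t", dtype={"tip_id": str})
    missing = [a for a in areas if a not in df.columns]
    if missing:
        raise ValueError(f"ranges table missing area columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        out[row["tip_id"]] = frozenset(a for a in areas if int(row[a]) == 1)
    return out


def write_ranges_tsv(path: str | Path, ranges: dict, areas: list[str]) -> None:
    rows = [
        {"tip_id": tip, **{a: int(a in r) for a in areas}}
        for tip, r in sorted(ranges.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=str(name), description="")
               for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# divtest report


def divtest_report(
    tree,
    n_total: int | None = None,
    mccr_replicates: int = 10000,
    event_times: dict | None = None,
    epsilons=(0.0, 0.5, 0.9),
    stem_age: float | None = None,
    seed: int = 0,
) -> dict:
    """The full diversification battery on one chronogram, as a JSON dict."""
    bt = branching_times(tree)
    gam = gamma_stat(bt)
    report: dict = {
        "n_tips": bt.n_tips,
        "crown_age": bt.crown_age,
        "gamma": {"gamma": gam.gamma, "p_one_tailed": gam.p_one_tailed},
    }
    if n_total is not None and n_total >= bt.n_tips:
        mccr = mccr_test(gam.gamma, n_total, bt.n_tips,
                         replicates=mccr_replicates, seed=seed)
        report["mccr"] = {
            "n_total": n_total,
            "n_sampled": bt.n_tips,
            "replicates": mccr_replicates,
            "critical_value": mccr.critical_value,
            "p_value": mccr.p_value,
        }
    fits = fit_all_models(bt)
    report["models"] = [
        {"model": f.model, "k": f.k, "lnl": f.lnl, "aic": f.aic,
         "params": {k: float(v) for k, v in f.params.items()}}
        for f in fits
    ]
    sel = delta_aic_rc(fits)
    report["model_selection"] = {
        "best_rc": sel["best_rc"].model,
        "best_rv": sel["best_rv"].model,
        "delta_aic_rc": sel["delta_aic_rc"],
        "lr": sel["lr"],
        "lr_p": sel["lr_p"],
    }
    shifts = {}
    for name, age in (event_times or EVENT_TIMES_MA).items():
        try:
            res = shift_at_time_test(bt, age)
        except TreeError as exc:
            shifts[name] = {"age": age, "error": str(exc)}
            continue
        shifts[name] = {
            "age": age, "lambda_before": res.lam_before,
            "lambda_after": res.lam_after, "lr": res.lr, "p": res.p_value,
        }
    report["shift_tests"] = shifts
    rc = rel_cladogenesis_test(tree)
    report["rel_cladogenesis"] = {
        "n_tested": len(rc.p_values),
        "any_significant": rc.any_significant,
        "min_p_bonferroni": float(np.min(rc.p_bonferroni)) if len(rc.p_values) else None,
    }
    n_div = n_total if n_total is not None else bt.n_tips
    report["net_diversification"] = [
        {
            "epsilon": eps,
            "r_crown": ms_netdiv(n_div, bt.crown_age, eps).r_crown,
            "r_stem": (ms_netdiv(n_div, stem_age, eps).r_stem
                       if stem_age else None),
        }
        for eps in epsilons
    ]
    return report


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Settings for an end-to-end run; any stage may be omitted."""

    tree: str | Path | None = None            # phylogram for ultrametricize
    chronogram: str | Path | None = None      # externally dated tree
    alignment: str | Path | None = None       # FASTA for consensus reduction
    ranges: str | Path | None = None          # tip-by-area TSV
    dec_model: str | Path | None = None       # YAML/JSON paleogeographic model
    outgroups: list = dc_field(default_factory=list)
    clades: dict = dc_field(default_factory=dict)   # name -> [tipA, tipB]
    root_age: float = 1.0
    maxareas: int | None = None
    n_total: int | None = None
    mccr_replicates: int = 10000
    event_times: dict = dc_field(default_factory=lambda: dict(EVENT_TIMES_MA))
    stem_age: float | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the requested stages in order, writing per-stage artifacts.

    Inputs are never modified; every artifact is a new file under
    ``out_dir``.  A stage failure raises with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    clusters = None

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            if result is not None:
                report["stages"][name] = result
        return deco

    chrono = None
    if config.tree is not None:
        @stage("ultrametricize")
        def _ultra():
            nonlocal chrono
            phylogram = read_tree(Path(config.tree))
            res = mpl_ultrametricize(phylogram, root_age=config.root_age)
            (out / "chronogram.nwk").write_text(res.newick() + "\n")
            chrono = res.tree
            clock = None
            if res.clock is not None:
                clock = {
                    "n_tested": res.clock.n_tested,
                    "rejected": res.clock.rejected,
                }
            return {"root_age": config.root_age, "clock_test": clock,
                    "out": "chronogram.nwk"}

    if config.chronogram is not None:
        chrono = as_chronogram(read_tree(Path(config.chronogram)), snap=True)

    if chrono is None:
        raise RuntimeError("pipeline needs a tree or a chronogram input")

    if config.outgroups:
        chrono = prune_tips(chrono, config.outgroups)
        chrono = as_chronogram(chrono, snap=True)
        (out / "ingroup.nwk").write_text(write_newick(chrono) + "\n")

    @stage("delimit")
    def _delimit():
        nonlocal clusters
        fit = gmyc_fit(chrono)
        clusters = fit.clusters
        rows = [
            {"tip_id": tip, "cluster_id": cid,
             "cluster_type": fit.cluster_types[cid]}
            for tip, cid in sorted(fit.clusters.items())
        ]
        pd.DataFrame(rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        lo, hi = fit.entity_range
        summary = {
            "n_entities": fit.n_entities,
            "threshold": fit.params.threshold,
            "logl_gmyc": fit.logl_gmyc,
            "logl_null": fit.logl_null,
            "lrt_2dL": fit.lrt,
            "df": fit.df,
            "p_value": fit.p_value,
            "entity_range_2lnl": [lo, hi],
        }
        (out / "gmyc.json").write_text(json.dumps(summary, indent=2))
        return summary

    if config.alignment is not None:
        @stage("reduce")
        def _reduce():
            aln = read_fasta(Path(config.alignment))
            cons = consensus_reduce(aln, clusters)
            write_fasta(out / "consensus.fasta",
                        {f"cluster{cid}": seq for cid, seq in sorted(cons.items())})
            return {"n_sequences": len(cons), "out": "consensus.fasta"}

    if config.ranges is not None and config.dec_model is not None:
        @stage("dec")
        def _dec():
            cfg = load_model_config(Path(config.dec_model))
            if config.maxareas is not None:
                cfg["maxareas"] = config.maxareas
            model, space, root_range = model_from_config(cfg)
            ranges = read_ranges_tsv(Path(config.ranges), list(model.areas))
            fit = dec_optimize(chrono, ranges, model, space,
                               root_range=root_range)
            rows = []
            for entry in fit.node_table:
                for cand in entry["candidates"]:
                    rows.append({
                        "node": entry["node"], "age": entry["age"],
                        "range": cand["range"], "split": cand["split"] or "",
                        "lnl": cand["lnl"],
                    })
            pd.DataFrame(rows).to_csv(out / "dec_nodes.tsv", sep="\t", index=False)
            summary = {"d": fit.d, "e": fit.e, "lnl": fit.lnl,
                       "warning": fit.boundary_warning}
            (out / "dec.json").write_text(json.dumps(summary, indent=2))
            return summary

    @stage("divtest")
    def _divtest():
        results = {"full_tree": divtest_report(
            chrono, n_total=config.n_total,
            mccr_replicates=config.mccr_replicates,
            event_times=config.event_times, stem_age=config.stem_age,
            seed=config.seed,
        )}
        for name, pair in config.clades.items():
            sub = as_chronogram(extract_clade(chrono, pair), snap=True)
            results[name] = divtest_report(
                sub, event_times=config.event_times, seed=config.seed,
            )
        (out / "divtest.json").write_text(json.dumps(results, indent=2))
        bt = branching_times(chrono)
        ltt_table(bt).to_csv(out / "ltt.tsv", sep="\t", index=False)
        return {k: {"gamma": v["gamma"]["gamma"]} for k, v in results.items()}

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
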