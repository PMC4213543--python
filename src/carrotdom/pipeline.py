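"""End-to-end orchestration with a reproducibility manifest.

`run_all` executes the stages of the domestication analysis in dependency
order - simulate (or load) a pooled pileup, call SNPs, compute diversity
and differentiation statistics, build/project/fold the joint SFS, fit the
demographic model variants, and run the expression contrast - from a
single YAML-style config dict.  Any stage can be skipped; every
stochastic stage takes an explicit seed defaulting from the master seed,
and a manifest (config snapshot, seeds, input checksums, per-stage
outputs, package version) is written so reruns are bit-for-bit
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path


import pandas as pd

from . import __version__
from . import caller, demography, expression, io_formats, popgen, simulate
from .sfs import build_sfs, fold

DEFAULT_STAGES = ("pileup", "call", "stats", "sfs", "fit", "expression")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: dict, stage: str, offset: int) -> int:
    return int(config.get(stage, {}).get("seed", int(config.get("seed", 0)) + offset))


def run_all(config: dict, outdir=None) -> dict:
    """Run the configured stages; returns the manifest dict.

    Raises with a stage-labelled message on failure.
    """
    outdir = Path(outdir or config.get("outdir", "carrotdom_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {
        "version": __version__,
        "config": config,
        "stages": {},
        "inputs": {},
    }
    state: dict = {}
    for stage in stages:
        try:
            _STAGES[stage](config, outdir, manifest, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _record(manifest, stage, seed=None, **outputs):
    entry = {"outputs": {k: str(v) for k, v in outputs.items()}}
    if seed is not None:
        entry["seed"] = seed
    manifest["stages"][stage] = entry


def _stage_pileup(config, outdir, manifest, state):
    cfg = config.get("pileup", {})
    if "path" in cfg:
        path = Path(cfg["path"])
        state["pileup"] = io_formats.read_pileup_tsv(path)
        manifest["inputs"][str(path)] = _sha256(path)
        _record(manifest, "pileup", input=path)
        return
    seed = _stage_seed(config, "pileup", 1)
    sim_cfg = simulate.PileupSimConfig(
        **{**cfg.get("simulate", {}), "seed": seed}
    )
    pileup, truth = simulate.simulate_pooled_pileup(sim_cfg)
    out = outdir / "pileup.tsv"
    io_formats.write_pileup_tsv(pileup, out)
    truth.to_csv(outdir / "pileup_truth.tsv", sep="\t", index=False)
    state["pileup"] = pileup
    _record(manifest, "pileup", seed=seed, pileup=out)


def _stage_call(config, outdir, manifest, state):
    cfg = config.get("call", {})
    pileup = state["pileup"]
    sample_ids = sorted(set(pileup["sample_id"]))
    pools = cfg.get("pools") or {s: 3 for s in sample_ids}
    groups = cfg.get("groups") or {
        s: ("cultivated" if i < len(sample_ids) // 2 else "wild")
        for i, s in enumerate(sample_ids)
    }
    gm = caller.call_pileup(
        pileup, pools, exclude=tuple(cfg.get("exclude", ())), groups=groups
    )
    gm = caller.select_snp_sites(gm, max_missing=int(cfg.get("max_missing", 1)))
    out = outdir / "calls.vcf"
    io_formats.write_vcf(gm, out)
    io_formats.write_groups_tsv(groups, outdir / "groups.tsv")
    state["genotypes"] = gm
    _record(manifest, "call", calls=out, n_snps=gm.n_loci)


def _stage_stats(config, outdir, manifest, state):
    cfg = config.get("stats", {})
    gm = state["genotypes"]
    seed = _stage_seed(config, "stats", 2)
    group_names = sorted(set(gm.groups.values()))
    table = popgen.diversity_table(
        gm, group_names, L=cfg.get("L"), per_kb=bool(cfg.get("per_kb", False)),
        n_boot=int(cfg.get("boot", 1000)), seed=seed,
    )
    rows = []
    for est in table:
        row = {"group": est.group}
        for k in ("He", "P", "theta_pi", "theta_w", "tajimas_D"):
            row[k] = getattr(est, k if k != "tajimas_D" else "tajimas_D")
            row[f"{k}_lo"], row[f"{k}_hi"] = est.ci[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(group_names) == 2:
        f = popgen.fst(gm, group_names[0], group_names[1],
                       estimator=cfg.get("fst_estimator", "hudson"))
        lo, hi = popgen.bootstrap_ci(
            lambda m: popgen.fst(m, group_names[0], group_names[1]).fst,
            gm, n_boot=int(cfg.get("boot", 1000)), seed=seed + 1,
        )
        df.attrs["fst"] = f.fst
        pd.DataFrame([{"fst": f.fst, "lo": lo, "hi": hi}]).to_csv(
            outdir / "fst.tsv", sep="\t", index=False
        )
    out = outdir / "diversity.tsv"
    df.to_csv(out, sep="\t", index=False)
    state["diversity"] = df
    _record(manifest, "stats", seed=seed, diversity=out)


def _stage_sfs(config, outdir, manifest, state):
    cfg = config.get("sfs", {})
    gm = state["genotypes"]
    groups = tuple(cfg.get("groups", sorted(set(gm.groups.values()))))
    target = tuple(cfg["project"]) if cfg.get("project") else None
    # building straight onto the projection grid keeps loci with missing
    # calls (per-locus hypergeometric projection) instead of dropping them
    spec = build_sfs(gm, groups, polarized=bool(cfg.get("polarized", False)),
                     target_sizes=target)
    if cfg.get("fold", True) and not spec.folded:
        spec = fold(spec)
    out = outdir / "data.sfs"
    io_formats.write_sfs(spec, out)
    state["sfs"] = spec
    _record(manifest, "sfs", sfs=out)


def _stage_fit(config, outdir, manifest, state):
    cfg = config.get("fit", {})
    seed = _stage_seed(config, "fit", 3)
    comparison = demography.compare_models(
        state["sfs"], seed=seed,
        n_starts=int(cfg.get("starts", 8)),
        reps=int(cfg.get("reps", 200)),
        maxfev=int(cfg.get("maxfev", 200)),
    )
    payload = {
        v: {
            "params": dataclasses.asdict(f.params),
            "loglik": f.loglik,
            "theta_hat": f.theta_hat,
        }
        for v, f in comparison["fits"].items()
    }
    payload["lrt"] = comparison["lrt"]
    out = outdir / "fit.json"
    out.write_text(json.dumps(payload, indent=2))
    state["fit"] = comparison
    _record(manifest, "fit", seed=seed, fit=out)


def _stage_expression(config, outdir, manifest, state):
    cfg = config.get("expression", {})
    seed = _stage_seed(config, "expression", 4)
    if "coverage" in cfg:
        path = Path(cfg["coverage"])
        cov = io_formats.read_coverage_tsv(path)
        groups = io_formats.read_groups_tsv(cfg["groups"])
        table = expression.ExpressionTable(cov, groups)
        manifest["inputs"][str(path)] = _sha256(path)
    else:
        sim_cfg = simulate.ExpressionSimConfig(
            **{**cfg.get("simulate", {}), "seed": seed}
        )
        table, truth = simulate.simulate_expression_table(sim_cfg)
        truth.to_csv(outdir / "expression_truth.tsv", sep="\t")
    norm = expression.normalize_coverage(table)
    d = expression.expression_difference(norm)
    mean_d, lo, hi = expression.mean_difference_ci(
        d, n_boot=int(cfg.get("boot", 1000)), seed=seed + 1
    )
    uniq_c, uniq_w = expression.call_unique_expression(table)
    hist = expression.histogram(d, bin_width=float(cfg.get("bin_width", 0.1)))
    d.to_frame().to_csv(outdir / "expression_diff.tsv", sep="\t")
    hist.to_csv(outdir / "expression_hist.tsv", sep="\t", index=False)
    summary = {
        "mean_d": mean_d, "ci": [lo, hi],
        "unique_cultivated": uniq_c, "unique_wild": uniq_w,
    }
    (outdir / "expression_summary.json").write_text(json.dumps(summary, indent=2))
    state["expression"] = summary
    _record(manifest, "expression", seed=seed,
            diff=outdir / "expression_diff.tsv")


_STAGES = {
    "pileup": _stage_pileup,
    "call": _stage_call,
    "stats": _stage_stats,
    "sfs": _stage_sfs,
    "fit": _stage_fit,
    "expression": _stage_expression,
}
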