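"""End-to-end study workflow: diversity -> neutrality -> mismatch -> structure
-> network -> dating, from one configuration, with reproducible seeding.

One global seed deterministically derives per-stage seeds (stable CRC hashing
of the stage name) so any stage can be re-run in isolation and reproduce the
full-pipeline result.  Stages that fail are recorded and skipped, and stages
depending on them are marked skipped-dependent.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, dating, diversity, mismatch, network, neutrality, seq_io, structure
from .errors import HaplostatError

logger = logging.getLogger("haplostat")

STAGES = ("diversity", "neutrality", "mismatch", "structure", "network", "dating")
_DEPENDS = {"dating": ("mismatch",)}


@dataclass
class RunConfig:
    alignment: str | Path
    metadata: str | Path
    out_dir: str | Path
    grouping: str = "region"
    n_perm: int = 1000
    n_boot: int = 1000
    n_sims: int = 1000
    mu: float = dating.DEFAULT_MU
    alpha: float = 0.95
    correction_factor: float = dating.DEFAULT_CORRECTION
    mismatch_model: str = "demographic"
    seed: int = 0
    skip: tuple[str, ...] = ()

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _header(config: RunConfig) -> str:
    digest = zlib.crc32(
        json.dumps(
            {k: str(v) for k, v in vars(config).items() if k != "out_dir"},
            sort_keys=True,
        ).encode()
    )
    return f"# haplostat {__version__} config_digest={digest:08x} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=index)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns a report dict (also written as run_log.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in vars(config).items()},
        "stages": {},
    }

    try:
        aln = seq_io.read_alignment(config.alignment)
        meta = seq_io.read_metadata(config.metadata)
        seq_io.check_metadata(aln, meta)
    except HaplostatError:
        raise
    group_of = dict(zip(meta["sample_id"], meta[config.grouping]))
    groups = list(dict.fromkeys(meta[config.grouping]))
    fits: dict[str, mismatch.MismatchFit] = {}

    def sub_alignment(g):
        return aln.subset([i for i in aln.ids if group_of[i] == g])

    def run_stage(name, fn):
        if name in config.skip:
            report["stages"][name] = {"status": "skipped"}
            logger.info("stage %s skipped by config", name)
            return
        for dep in _DEPENDS.get(name, ()):
            if report["stages"].get(dep, {}).get("status") != "ok":
                report["stages"][name] = {"status": "skipped-dependent", "missing": dep}
                logger.warning("stage %s skipped: dependency %s unavailable", name, dep)
                return
        t0 = time.time()
        try:
            fn()
        except Exception as exc:  # isolate per-stage failures
            report["stages"][name] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
            logger.exception("stage %s failed", name)
        else:
            report["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
                "seed": config.stage_seed(name),
            }
            logger.info("stage %s done in %.2fs", name, time.time() - t0)

    # -- diversity ---------------------------------------------------------
    def stage_diversity():
        df = diversity.summarize(aln, meta, grouping=config.grouping)
        _write_csv(df.round(5), out / "diversity.csv", config)

    # -- neutrality --------------------------------------------------------
    def stage_neutrality():
        seed = config.stage_seed("neutrality")
        rows = {}
        for idx, g in enumerate(groups + ["all"]):
            sub = aln if g == "all" else sub_alignment(g)
            if sub.n < 4:
                rows[g] = {"n": sub.n, "D": np.nan, "p_D": np.nan,
                           "Fs": np.nan, "p_Fs": np.nan}
                continue
            res = neutrality.analyze_alignment(sub, n_sims=config.n_sims, seed=seed + idx)
            rows[g] = {
                "n": sub.n,
                "D": res.D,
                "p_D": res.p_D,
                "Fs": res.Fs,
                "p_Fs": res.p_Fs,
            }
        _write_csv(pd.DataFrame.from_dict(rows, orient="index"), out / "neutrality.csv", config)

    # -- mismatch ----------------------------------------------------------
    def stage_mismatch():
        seed = config.stage_seed("mismatch")
        rows = {}
        hist_frames = []
        for idx, g in enumerate(groups + ["all"]):
            sub = aln if g == "all" else sub_alignment(g)
            if sub.n < 3:
                continue
            hist = mismatch.observed_mismatch(sub)
            hist_frames.append(
                pd.DataFrame({"group": g, "differences": np.arange(hist.counts.size),
                              "count": hist.counts})
            )
            try:
                fit = mismatch.fit_expansion(hist, model=config.mismatch_model)
                fit = mismatch.bootstrap_gof(
                    fit, (sub.n, sub.L), B=config.n_boot, seed=seed + idx
                )
            except HaplostatError as exc:
                logger.warning("mismatch fit failed for %s: %s", g, exc)
                continue
            fits[g] = fit
            row = {"n": sub.n, "model": fit.model}
            for pname, val in fit.params().items():
                row[pname] = val
                if pname in fit.ci:
                    row[f"{pname}_ci_low"], row[f"{pname}_ci_high"] = fit.ci[pname]
            row.update(SSD=fit.SSD, p_SSD=fit.p_SSD, RAG=fit.RAG, p_RAG=fit.p_RAG)
            rows[g] = row
        _write_csv(pd.concat(hist_frames), out / "mismatch_histograms.csv", config, index=False)
        _write_csv(pd.DataFrame.from_dict(rows, orient="index"), out / "mismatch_fits.csv", config)

    # -- structure ---------------------------------------------------------
    def stage_structure():
        seed = config.stage_seed("structure")
        pops = [group_of[i] for i in aln.ids]
        res = structure.amova(aln, pops, n_perm=config.n_perm, seed=seed)
        _write_csv(res.table(), out / "amova.csv", config)
        with open(out / "amova.csv", "a") as fh:
            for k, v in res.phi.items():
                fh.write(f"# {k}={v:.5f} p={res.p[k]:.5f}\n")
        pw = structure.pairwise_phist(aln, pops, n_perm=config.n_perm, seed=seed + 1)
        _write_csv(pw.to_frame().round(5), out / "pairwise_phist.csv", config)
        _write_csv(pw.p_frame().round(5), out / "pairwise_phist_p.csv", config)
        _write_csv(pw.sequential_bonferroni().round(5),
                   out / "pairwise_phist_p_corrected.csv", config)

    # -- network -----------------------------------------------------------
    def stage_network():
        table = seq_io.collapse_haplotypes(aln, meta, grouping=config.grouping)
        net = network.build_network(table, alpha=config.alpha)
        net.to_graphml(out / "network.graphml")
        _write_csv(net.node_table(), out / "network_nodes.csv", config, index=False)
        _write_csv(net.edge_table(), out / "network_edges.csv", config, index=False)

    # -- dating ------------------------------------------------------------
    def stage_dating():
        rows = {}
        for g, fit in fits.items():
            et = dating.expansion_time(
                fit.tau, mu=config.mu, L=aln.L, correction_factor=config.correction_factor
            )
            rows[g] = {
                "tau": fit.tau,
                "T_kyr_uncorrected": round(et.T_kyr, 3),
                "T_kyr_corrected": round(et.T_corrected_kyr, 3),
            }
        _write_csv(pd.DataFrame.from_dict(rows, orient="index"), out / "dating.csv", config)

    for name, fn in zip(
        STAGES,
        (stage_diversity, stage_neutrality, stage_mismatch, stage_structure,
         stage_network, stage_dating),
    ):
        run_stage(name, fn)

    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
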