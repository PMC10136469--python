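"""End-to-end orchestration: simulate (or load) -> preprocess ->
behavior -> IBS band selection -> interaction scan -> permutation ->
time-lag scan -> Granger causality -> classification -> summary.

Each stage writes its report files under ``out_dir/<stage>/`` together
with a ``.stage.json`` cache key derived from the config, the seed and
the upstream keys; a stage whose outputs already exist with a matching
key is not rewritten, and in-memory prerequisites are recomputed lazily
only when a stale downstream stage needs them.  A ``manifest.json``
snapshots the config, seed, package version and every artifact's
SHA-256.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_test, cohort_drt
from .classify import build_features, k_averaged_accuracy, label_permutation_p
from .config import AnalysisConfig
from .gca import cohort_granger, direction_test
from .ibs import (band_average, compute_cohort_ibs, dyad_permutation_test,
                  interaction_scan, select_band, timelag_scan)
from .preprocess import preprocess_cohort
from .simulate import gen_cohort

__all__ = ["run_all", "report", "PipelineError"]

log = logging.getLogger("hyperdyad")


class PipelineError(RuntimeError):
    pass


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    def __init__(self, out_dir: Path, name: str, key: str):
        self.dir = out_dir / name
        self.name = name
        self.key = key
        self.marker = self.dir / ".stage.json"

    @property
    def cached(self) -> bool:
        if not self.marker.exists():
            return False
        try:
            return json.loads(self.marker.read_text())["key"] == self.key
        except (json.JSONDecodeError, KeyError):
            return False

    def finish(self) -> None:
        self.marker.write_text(json.dumps({"key": self.key}) + "\n")

    def files(self) -> dict:
        return {f.name: _sha(f) for f in sorted(self.dir.glob("*"))
                if f.name != ".stage.json"}


def run_all(config: AnalysisConfig | None = None, out_dir: str | Path = "run",
            *, n_couples: int = 17, n_controls: int = 18,
            seed: int | None = None, sessions=None,
            covariate_names=("age_m", "age_f")) -> dict:
    """Run every stage on a synthetic cohort (or caller-provided
    ``sessions``) and write reports under ``out_dir``.  Returns the run
    manifest.  Stops with :class:`PipelineError` naming the stage on any
    failure; an empty selected band stops the run after band selection.
    """
    config = config or AnalysisConfig()
    config.validate()
    seed = config.rng_seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    base_key = _hash_obj({"config": cfg_dict, "seed": seed,
                          "n": [n_couples, n_controls],
                          "external": sessions is not None})

    # ---- lazy in-memory artifacts -------------------------------------
    state: dict = {}

    def _sessions():
        if "sessions" not in state:
            log.info("stage=simulate n=%d+%d seed=%d", n_couples, n_controls, seed)
            state["sessions"] = sessions if sessions is not None else gen_cohort(
                n_couples, n_controls, seed=seed)
        return state["sessions"]

    def _preprocessed():
        if "pre" not in state:
            t0 = time.time()
            kept, pairs, reports = preprocess_cohort(_sessions(), config)
            if len(kept) < 4:
                raise PipelineError("preprocess: fewer than 4 dyads survived QC")
            state["pre"] = (kept, pairs, reports)
            log.info("stage=preprocess kept=%d elapsed=%.1fs",
                     len(kept), time.time() - t0)
        return state["pre"]

    def _ibs():
        if "ibs" not in state:
            t0 = time.time()
            kept, pairs, _ = _preprocessed()
            state["ibs"] = compute_cohort_ibs(kept, pairs, config)
            log.info("stage=ibs dyads=%d elapsed=%.1fs",
                     state["ibs"].n_dyads, time.time() - t0)
        return state["ibs"]

    def _band():
        if "band" not in state:
            band_file = out / "ibs" / "band.json"
            if band_file.exists() and _Stage(out, "ibs", _key("ibs")).cached:
                info = json.loads(band_file.read_text())
                state["band"] = tuple(info["band_hz"]) if info["band_hz"] else None
            else:
                sel = _band_selection()
                state["band"] = sel.band_hz
        return state["band"]

    def _band_selection():
        if "band_sel" not in state:
            state["band_sel"] = select_band(_ibs(), config=config)
        return state["band_sel"]

    def _scan():
        if "scan" not in state:
            band = _band()
            if band is None:
                raise PipelineError(
                    "band selection returned an empty band: no frequency shows "
                    "a task-vs-rest IBS increase; downstream stages refuse to run")
            state["scan"] = interaction_scan(_ibs(), band, covariate_names, config)
        return state["scan"]

    def _scan_summary():
        """(survivors, hits, F): from the cached interaction stage when
        available, else from the in-memory scan."""
        d = out / "interaction"
        if _Stage(out, "interaction", _key("interaction")).cached:
            surv = pd.read_csv(d / "survivors.tsv", sep="\t")
            hits = pd.read_csv(d / "hits.tsv", sep="\t")
            f = np.loadtxt(d / "interaction_F.tsv", delimiter="\t", ndmin=2)
            return ([(int(r.ch_m), int(r.ch_f)) for r in surv.itertuples()],
                    [(int(r.ch_m), int(r.ch_f)) for r in hits.itertuples()], f)
        scan = _scan()
        return scan.survivors, scan.precorrection_hits, scan.F

    def _target_pair():
        survivors, hits, f = _scan_summary()
        for pairs_list in (survivors, hits):
            if pairs_list:
                return pairs_list[int(np.argmax(
                    [f[i - 1, j - 1] for i, j in pairs_list]))]
        f = np.nan_to_num(f, nan=-1.0)
        i, j = np.unravel_index(int(np.argmax(f)), f.shape)
        return (i + 1, j + 1)

    manifest_stages: dict = {}

    def _key(name: str) -> str:
        return _hash_obj({"base": base_key, "stage": name})

    def _run(name: str, fn):
        stage = _Stage(out, name, _key(name))
        if stage.cached:
            log.info("stage=%s cached", name)
        else:
            stage.dir.mkdir(parents=True, exist_ok=True)
            t0 = time.time()
            try:
                fn(stage.dir)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
            stage.finish()
            log.info("stage=%s elapsed=%.1fs", name, time.time() - t0)
        manifest_stages[name] = {"key": stage.key, "files": stage.files()}

    # ---- stages -------------------------------------------------------
    def st_behavior(d: Path):
        drt = cohort_drt(_sessions())
        covs = pd.DataFrame([s.covariates for s in _sessions()],
                            index=[s.dyad_id for s in _sessions()])
        ftab, simple = behavior_test(drt, covs, covariate_names)
        drt.table.to_csv(d / "drt.tsv", sep="\t", index=False)
        ftab.table.to_csv(d / "ancova.tsv", sep="\t", index=False)
        simple.to_csv(d / "simple_effects.tsv", sep="\t", index=False)

    def st_qc(d: Path):
        _, _, reports = _preprocessed()
        rows = []
        for rep in reports:
            for pid in rep.cv_pct:
                rows.append((pid, rep.bad_fraction[pid],
                             int(rep.bad_channels[pid].sum()), rep.excluded[pid]))
        pd.DataFrame(rows, columns=["participant_id", "bad_fraction",
                                    "n_bad_channels", "excluded"]) \
            .to_csv(d / "qc.tsv", sep="\t", index=False)

    def st_ibs(d: Path):
        sel = _band_selection()
        (d / "band.json").write_text(json.dumps({
            "band_hz": list(sel.band_hz) if sel.band_hz else None,
            "n_pairs": sel.n_pairs,
            "n_freqs": len(sel.freqs_hz)}, indent=1) + "\n")
        # per-frequency scan summary: strongest pair per frequency
        with np.errstate(invalid="ignore"):
            best = np.nanmax(np.nan_to_num(sel.t, nan=-np.inf), axis=(0, 1))
        pd.DataFrame({"freq_hz": sel.freqs_hz, "max_t": best,
                      "n_sig_pairs": sel.fdr_mask.sum(axis=(0, 1))}) \
            .to_csv(d / "band_scan.tsv", sep="\t", index=False)

    def st_interaction(d: Path):
        scan = _scan()
        np.savetxt(d / "interaction_F.tsv", scan.F, delimiter="\t", fmt="%.6g")
        np.savetxt(d / "interaction_p.tsv", scan.p, delimiter="\t", fmt="%.6g")
        pd.DataFrame(scan.survivors, columns=["ch_m", "ch_f"]) \
            .to_csv(d / "survivors.tsv", sep="\t", index=False)
        pd.DataFrame(scan.precorrection_hits, columns=["ch_m", "ch_f"]) \
            .to_csv(d / "hits.tsv", sep="\t", index=False)
        for pair, df in scan.simple_effects.items():
            df.to_csv(d / f"simple_effects_{pair[0]}_{pair[1]}.tsv",
                      sep="\t", index=False)
        # group x block band-z means at the target pair (the headline plot)
        ibs = _ibs()
        bz = band_average(ibs, _band())
        ci, cj = _target_pair()
        i1, i2 = ibs.seg_index("block1"), ibs.seg_index("block2")
        rows = []
        for g in ("couple", "control"):
            sel_idx = [k for k, gg in enumerate(ibs.groups) if gg == g]
            for b, si in ((1, i1), (2, i2)):
                vals = bz[sel_idx, ci - 1, cj - 1, si]
                rows.append((g, b, float(np.mean(vals)), float(np.std(vals, ddof=1))))
        pd.DataFrame(rows, columns=["group", "block", "mean_z", "sd_z"]) \
            .to_csv(d / "target_pair_means.tsv", sep="\t", index=False)

    def st_permutation(d: Path):
        kept, pairs, _ = _preprocessed()
        res = dyad_permutation_test(kept, pairs, _target_pair(), _band(),
                                    config, seed=seed + 1,
                                    covariates=covariate_names)
        (d / "permutation.json").write_text(json.dumps({
            "target_pair": [int(c) for c in res.target_pair],
            "observed_F": res.observed_F, "p": res.p, "n_iter": res.n_iter,
            "null_mean": float(res.null_F.mean())}, indent=1) + "\n")

    def st_lag(d: Path):
        kept, pairs, _ = _preprocessed()
        df = timelag_scan(kept, pairs, _target_pair(), _band(), config,
                          covariates=covariate_names)
        df.to_csv(d / "lag_scan.tsv", sep="\t", index=False)

    def st_gca(d: Path):
        kept, pairs, _ = _preprocessed()
        gc = cohort_granger(kept, pairs, _target_pair(), config)
        gc.to_csv(d / "gc.tsv", sep="\t", index=False)
        ftab, simple = direction_test(gc)
        ftab.table.to_csv(d / "direction_anova.tsv", sep="\t", index=False)
        simple.to_csv(d / "direction_simple.tsv", sep="\t", index=False)

    def st_classify(d: Path):
        feats = build_features(_scan(), _ibs(), _band())
        ks = tuple(k for k in config.knn_ks if k < len(feats.labels))
        result, _null = label_permutation_p(
            feats.features, feats.labels, config.knn_null_iterations,
            seed=seed + 2, ks=ks)
        pd.DataFrame({"k": result.ks, "accuracy": result.accuracy_per_k}) \
            .to_csv(d / "per_k.tsv", sep="\t", index=False)
        (d / "result.json").write_text(json.dumps({
            "feature_pairs": [list(p) for p in feats.feature_pairs],
            "mean_accuracy": result.mean_accuracy,
            "frac_k_above_chance": result.frac_k_above_chance,
            "null_mean": result.null_mean, "p": result.p,
            "n_null": result.n_null}, indent=1) + "\n")

    for name, fn in (("behavior", st_behavior), ("qc", st_qc), ("ibs", st_ibs),
                     ("interaction", st_interaction),
                     ("permutation", st_permutation), ("lag", st_lag),
                     ("gca", st_gca), ("classify", st_classify)):
        _run(name, fn)

    manifest = {"version": __version__, "seed": seed, "config": cfg_dict,
                "stages": manifest_stages}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n")
    (out / "summary.md").write_text(report(out))
    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable run summary assembled from the stage outputs."""
    out = Path(out_dir)

    def _load(rel):
        p = out / rel
        return json.loads(p.read_text()) if p.exists() else None

    def _tsv(rel):
        p = out / rel
        return pd.read_csv(p, sep="\t") if p.exists() else None

    lines = ["# Dyad competition analysis summary", ""]
    anc = _tsv("behavior/ancova.tsv")
    if anc is not None:
        inter = anc[anc["effect"] == "group:block"].iloc[0]
        lines += ["## Behavior (DRT)",
                  f"group x block interaction: F({inter.df_num:.0f},"
                  f"{inter.df_den:.0f}) = {inter.F:.2f}, p = {inter.p:.3f}, "
                  f"eta_p2 = {inter.eta_p2:.2f}", ""]
    band = _load("ibs/band.json")
    if band is not None:
        b = band["band_hz"]
        btxt = f"{b[0]:.2f}-{b[1]:.2f} Hz" if b else "EMPTY"
        lines += ["## Inter-brain synchrony",
                  f"selected frequency band: {btxt} "
                  f"({band['n_pairs']} channel pairs scanned)", ""]
    surv = _tsv("interaction/survivors.tsv")
    if surv is not None:
        pairs = ", ".join(f"({r.ch_m},{r.ch_f})" for r in surv.itertuples()) or "none"
        lines += [f"FDR-surviving group x block pairs: {pairs}"]
    means = _tsv("interaction/target_pair_means.tsv")
    if means is not None:
        for r in means.itertuples():
            lines += [f"  {r.group} block {r.block}: z = {r.mean_z:.3f} "
                      f"(sd {r.sd_z:.3f})"]
        lines += [""]
    perm = _load("permutation/permutation.json")
    if perm is not None:
        lines += [f"dyad-recombination permutation: observed F = "
                  f"{perm['observed_F']:.2f}, p = {perm['p']:.4g} "
                  f"({perm['n_iter']} iterations)", ""]
    lag = _tsv("lag/lag_scan.tsv")
    if lag is not None:
        peak = lag.iloc[lag["F"].idxmax()]
        lines += [f"time-lag scan: max F = {peak.F:.2f} at lag "
                  f"{peak.lag_s:+.0f} s", ""]
    danova = _tsv("gca/direction_anova.tsv")
    dsimple = _tsv("gca/direction_simple.tsv")
    if danova is not None:
        inter = danova[danova["effect"] == "direction:block"].iloc[0]
        lines += ["## Directional coupling (couples)",
                  f"direction x block: F = {inter.F:.2f}, p = {inter.p:.3f}"]
        if dsimple is not None:
            for r in dsimple.itertuples():
                lines += [f"  block {r.block}: t = {r.t:.2f}, p = {r.p:.3f}"]
        lines += [""]
    cls = _load("classify/result.json")
    if cls is not None:
        lines += ["## Classification",
                  f"k-averaged LOO accuracy = {100 * cls['mean_accuracy']:.2f}% "
                  f"(chance-null mean {100 * cls['null_mean']:.1f}%, "
                  f"p = {cls['p']:.4g})", ""]
    return "\n".join(lines)
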