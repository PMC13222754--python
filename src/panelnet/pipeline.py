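"""Study orchestration: simulate/ingest -> score -> networks -> comparisons.

Runs the full design: 9 cross-sectional networks (3 groups x 3 waves,
8 nodes including the two time-invariant cultural variables), pairwise
group and wave network comparison tests, 3 longitudinal panel GVARs with
pruning and bootstrap stability, and pairwise longitudinal edge
permutation tests.  Stage outputs are cached under the output directory
and keyed by a config hash, so a rerun resumes from finished stages; the
final ``report.json`` contains no timestamps and is byte-identical across
reruns of one configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import gvar as gv
from . import scoring as sco
from . import synthetic as syn
from .ggm import estimate_ggm
from .gvar import NODES

log = logging.getLogger("panelnet")

__all__ = ["StudyConfig", "run_study", "read_scores_csv",
           "write_scores_csv"]

XNODES = NODES + ["cAtt", "cPra"]   # cross-sectional networks use 8 nodes
WAVES = (3, 5, 9)


@dataclass
class StudyConfig:
    """Everything a study run needs; YAML round-trippable."""

    mode: str = "simulate"              # simulate | csv
    scenario: str = "shared"
    n_per_group: int | None = None      # None = study sizes 1167/614/627
    scores_csv: str | None = None
    items: bool = True
    groups: tuple = ("G1", "G2", "G3")
    waves: tuple = WAVES
    gamma: float = 0.5
    n_lambda: int = 100
    prune_alpha: float = 0.01
    n_boot: int = 200
    n_perm: int = 200
    paper_scale: bool = False           # n_boot = n_perm = 1000
    run_nct: bool = True
    run_longitudinal_permutation: bool = True
    covariates: tuple = ()              # optional demographic covariate hook
    seed: int = 0
    out: str = "out"
    verbosity: str = "INFO"

    def __post_init__(self):
        if self.paper_scale:
            self.n_boot = 1000
            self.n_perm = 1000
        if self.mode not in ("simulate", "csv"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "csv" and not self.scores_csv:
            raise ValueError("csv mode requires scores_csv")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        d = asdict(self)
        d.pop("out", None)
        d.pop("verbosity", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def estimator(self) -> dict:
        return {"gamma": self.gamma, "n_lambda": self.n_lambda}


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

SCORE_COLS = ["person_id", "group", "wave"] + NODES + ["cAtt", "cPra",
                                                       "included"]


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    df = scores.copy()
    for c in SCORE_COLS:
        if c not in df.columns:
            df[c] = True if c == "included" else np.nan
    df[SCORE_COLS].to_csv(path, index=False, float_format="%.10g")


def read_scores_csv(path, groups=("G1", "G2", "G3")) -> pd.DataFrame:
    """Read a score table; malformed rows are reported with line numbers."""
    df = pd.read_csv(path)
    missing = set(SCORE_COLS) - {"included"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_wave = ~df["wave"].isin(WAVES)
    if bad_wave.any():
        lines = (np.where(bad_wave)[0] + 2).tolist()[:5]
        raise ValueError(f"{path}: bad wave codes at lines {lines}")
    bad_grp = ~df["group"].isin(groups)
    if bad_grp.any():
        lines = (np.where(bad_grp)[0] + 2).tolist()[:5]
        raise ValueError(f"{path}: unknown group labels at lines {lines}")
    if "included" not in df.columns:
        df["included"] = True
    df["included"] = df["included"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage(outdir: Path, name: str, manifest: dict, fn):
    """Run a stage unless a cached output with a matching hash exists."""
    t0 = time.perf_counter()
    marker = outdir / f".stage_{name}.json"
    if marker.exists():
        cached = json.loads(marker.read_text())
        if cached.get("config_hash") == manifest["config_hash"]:
            log.info("stage %s: cached", name)
            return cached["payload"]
    payload = fn()
    marker.write_text(json.dumps(
        {"config_hash": manifest["config_hash"], "payload": payload},
        default=_jsonable))
    manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_jsonable))
    return payload


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_study(config: StudyConfig) -> dict:
    """Execute all stages and return the report dictionary.

    The report is also written to ``<out>/report.json``; individual stage
    outputs (scores.csv, ggm_*.json, gvar_*.json, comparison_*.csv) land
    in the same directory.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, 20),
                        format="%(message)s")
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.hash(), "stages": {},
                "config": asdict(config)}
    seeds = _spawn_seeds(config.seed, 8)
    report = {"provenance": {"config_hash": config.hash(),
                             "seed": config.seed,
                             "version": _version()}}

    # -- ingest / simulate ---------------------------------------------------
    if config.mode == "simulate":
        panel = syn.generate_study(config.scenario, config.n_per_group,
                                   seed=seeds[0], items=config.items)
        scores = panel.scores
        (outdir / "truth.json").write_text(panel.truth.to_json())
        if panel.items is not None:
            panel.items.to_csv(outdir / "items.csv", index=False)
    else:
        scores = read_scores_csv(config.scores_csv, config.groups)
        panel = None

    # -- inclusion filter (applied once, before all estimation) -------------
    counts = scores.dropna(subset=["irr"]).groupby("person_id")[
        "wave"].nunique()
    scores = scores.copy()
    scores["included"] = scores["person_id"].map(
        lambda i: counts.get(i, 0) >= 2)
    n_excl = int((~scores.drop_duplicates("person_id")["included"]).sum())
    log.info("inclusion filter: %d persons excluded (<2 waves of "
             "irritability)", n_excl)
    analytic = scores[scores["included"]].reset_index(drop=True)
    write_scores_csv(scores, outdir / "scores.csv")
    report["inclusion"] = {
        "excluded_persons": n_excl,
        "analytic_persons": int(analytic["person_id"].nunique()),
    }

    # -- reliability + descriptives -----------------------------------------
    def _descriptives():
        desc = []
        for v in NODES:
            for w in config.waves:
                try:
                    desc.append(sco.describe_by_group(analytic, v, w))
                except sco.ScoringError as e:
                    log.warning("descriptives %s wave %s: %s", v, w, e)
        out = {"anova": desc}
        corr = {}
        for w in config.waves:
            corr[str(w)] = sco.pearson_matrix(
                analytic, w, XNODES).round(6).values.tolist()
        out["correlations"] = {"nodes": XNODES, "by_wave": corr}
        (outdir / "descriptives.json").write_text(
            json.dumps(out, indent=1, default=_jsonable))
        return out

    report["descriptives"] = _stage(outdir, "descriptives", manifest,
                                    _descriptives)

    if config.mode == "simulate" and panel is not None \
            and panel.items is not None:
        def _reliab():
            items_inc = panel.items[panel.items["person_id"].isin(
                set(analytic["person_id"]))]
            rel = sco.reliability_report(items_inc)
            (outdir / "reliability.json").write_text(
                json.dumps(rel, indent=1, default=_jsonable))
            return rel
        report["reliability"] = _stage(outdir, "reliability", manifest,
                                       _reliab)

    # -- cross-sectional GGMs (3 groups x 3 waves) ---------------------------
    # optional demographic covariates simply join the node set
    xnodes = XNODES + [c for c in config.covariates
                       if c in analytic.columns]

    def _ggms():
        nets = {}
        for g in config.groups:
            for w in config.waves:
                sub = analytic[(analytic["group"] == g)
                               & (analytic["wave"] == w)][xnodes]
                net = estimate_ggm(sub, xnodes, group=g, wave=w,
                                   **config.estimator())
                nets[f"{g}_{w}"] = net.to_dict()
                (outdir / f"ggm_{g}_{w}.json").write_text(
                    json.dumps(net.to_dict(), default=_jsonable))
                _write_edge_csv(net, outdir / f"edges_{g}_{w}.csv")
        return nets

    report["cross_sectional"] = _stage(outdir, "ggm", manifest, _ggms)

    # -- NCTs: group pairs per wave, wave pairs per group --------------------
    if config.run_nct:
        def _ncts():
            out = []
            pairs = list(itertools.combinations(config.groups, 2))
            sub_seed = _spawn_seeds(seeds[2], len(pairs) * len(config.waves)
                                    + 3 * len(config.groups))
            k = 0
            for w in config.waves:
                for ga, gb in pairs:
                    da = analytic[(analytic["group"] == ga)
                                  & (analytic["wave"] == w)][XNODES].dropna()
                    db = analytic[(analytic["group"] == gb)
                                  & (analytic["wave"] == w)][XNODES].dropna()
                    res = cmp.nct_edges(da, db, config.estimator(),
                                        n_perm=config.n_perm,
                                        seed=sub_seed[k])
                    k += 1
                    frame = cmp.comparisons_to_frame(res["edges"])
                    frame["contrast"] = f"{ga}-{gb}@{w}"
                    frame.to_csv(outdir / f"comparison_{ga}-{gb}_w{w}.csv",
                                 index=False)
                    out.append({"wave": w, "groups": [ga, gb],
                                "omnibus": res["omnibus"],
                                "edges": frame.to_dict("records")})
            wave_pairs = list(itertools.combinations(config.waves, 2))
            for g in config.groups:
                gsc = analytic[analytic["group"] == g]
                for wx, wy in wave_pairs:
                    try:
                        res = cmp.nct_waves(gsc, wx, wy, XNODES,
                                            config.estimator(),
                                            n_perm=config.n_perm,
                                            seed=sub_seed[k % len(sub_seed)])
                    except ValueError as e:
                        log.warning("nct_waves %s %s-%s: %s", g, wx, wy, e)
                        continue
                    k += 1
                    frame = cmp.comparisons_to_frame(res["edges"])
                    frame["contrast"] = f"{g}@{wx}-{wy}"
                    frame.to_csv(outdir / f"comparison_{g}_w{wx}-w{wy}.csv",
                                 index=False)
                    out.append({"group": g, "waves": [wx, wy],
                                "edges": frame.to_dict("records")})
            return out

        report["nct"] = _stage(outdir, "nct", manifest, _ncts)

    # -- longitudinal panel GVARs with bootstrap -----------------------------
    def _gvars():
        out = {}
        bs_seeds = _spawn_seeds(seeds[4], len(config.groups))
        for i, g in enumerate(config.groups):
            gsc = analytic[analytic["group"] == g]
            fit = gv.fit_panel_gvar(gsc, NODES, waves=config.waves)
            pruned = gv.prune(fit, config.prune_alpha)
            boots = gv.bootstrap_edges(gsc, NODES, waves=config.waves,
                                       R=config.n_boot,
                                       alpha=config.prune_alpha,
                                       seed=bs_seeds[i], base_fit=fit)
            stable = gv.stable_network(pruned, boots)
            d = pruned.to_dict()
            d["bootstrap"] = boots.to_dict()
            d["stable_temporal"] = stable.beta.tolist()
            d["stable_contemporaneous"] = stable.omega_zeta.tolist()
            d["stable_between"] = stable.omega_b.tolist()
            (outdir / f"gvar_{g}.json").write_text(
                json.dumps(d, default=_jsonable))
            _write_gvar_edges(pruned, boots, stable,
                              outdir / f"gvar_{g}_edges.csv")
            out[g] = d
        return out

    report["longitudinal"] = _stage(outdir, "gvar", manifest, _gvars)

    # -- longitudinal edge permutation tests ---------------------------------
    if config.run_longitudinal_permutation:
        def _long_perm():
            out = []
            pairs = list(itertools.combinations(config.groups, 2))
            pseeds = _spawn_seeds(seeds[6], len(pairs))
            for (ga, gb), s in zip(pairs, pseeds):
                res = cmp.permutation_edge_test_longitudinal(
                    analytic[analytic["group"] == ga],
                    analytic[analytic["group"] == gb],
                    nodes=NODES, waves=config.waves,
                    n_perm=config.n_perm, alpha=config.prune_alpha, seed=s)
                frame = cmp.comparisons_to_frame(res["edges"])
                frame["contrast"] = f"{ga}-{gb}"
                frame.to_csv(outdir / f"comparison_long_{ga}-{gb}.csv",
                             index=False)
                out.append({"groups": [ga, gb],
                            "edges": frame.to_dict("records")})
            return out

        report["longitudinal_comparison"] = _stage(
            outdir, "long_perm", manifest, _long_perm)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable))
    return report


def _write_edge_csv(net, path):
    rows = []
    p = len(net.nodes)
    for i in range(p):
        for j in range(i + 1, p):
            w = float(net.edges[i, j])
            if w != 0.0:
                rows.append({"node_i": net.nodes[i], "node_j": net.nodes[j],
                             "weight": w})
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, index=False)


def _write_gvar_edges(fit, boots, stable, path):
    rows = []
    for kind, frm, to in boots.edges:
        est = gv.edge_value(fit, kind, frm, to) \
            if gv._edge_included(fit, kind, frm, to) else 0.0
        pr = boots.proportion(kind, frm, to)
        k = kind
        if kind == "temporal" and frm == to:
            k = "autoregressive"
        rows.append({"kind": k, "from": frm, "to": to, "estimate": est,
                     "inclusion_prop": pr,
                     "stable": bool(pr >= boots.threshold and est != 0.0)})
    pd.DataFrame(rows).to_csv(path, index=False)


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("panelnet")
    except PackageNotFoundError:  # pragma: no cover
        return "0.0.0"
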