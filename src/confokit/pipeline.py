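"""End-to-end orchestration: simulate → analyze → report.

A run is described by a :class:`RunConfig` (a stage list plus per-stage
parameter blocks and one global seed).  The global seed fans out to
independent per-stage substreams through ``numpy.random.SeedSequence``, so
rerunning any stage in isolation with its substream reproduces its
in-pipeline output, and identical config+seed gives identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ckio
from . import simulate
from .qens import analyze_temperature_series
from .sas import ga_select, guinier_fit, nnls_weights
from .smfret import compute_fret, displacement, fit_fret_histogram, stasi
from .thermal import delta_tm, fit_boltzmann

__all__ = ["RunConfig", "RunReport", "run", "stage_seed", "acceptance_check"]

log = logging.getLogger("confokit.pipeline")

KNOWN_STAGES = ("fret", "qens", "sas", "melt")


@dataclass
class RunConfig:
    stages: list[str]
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}; "
                             f"known: {list(KNOWN_STAGES)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(stages=raw["stages"], params=raw.get("params", {}),
                   seed=int(raw.get("seed", 0)),
                   out_dir=raw.get("out_dir"))

    def digest(self) -> str:
        blob = json.dumps({"stages": self.stages, "params": self.params,
                           "seed": self.seed}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_digest: str
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    failed: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_digest": self.config_digest, "seed": self.seed,
                       "stages": self.stages, "outputs": self.outputs,
                       "failed": self.failed}, fh, indent=2, default=str)


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent, reproducible substream seed for one stage."""
    idx = KNOWN_STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


# --- stage implementations -------------------------------------------------

def _stage_fret(p: dict, seed: int, out: Path | None) -> dict:
    cfg = simulate.FretSimConfig(seed=seed, **p.get("sim", {}))
    traces = simulate.simulate_fret_traces(cfg)
    fret = [compute_fret(t) for t in traces]
    model = stasi(fret)
    hist = fit_fret_histogram(fret, model.means,
                              n_bins=p.get("bins", 50),
                              rng=np.random.default_rng(seed + 1))
    r0 = p.get("r0", 54.8)
    ref = float(model.means[-1])       # highest-FRET state = inactive reference
    disp = {f"{m:.2f}": displacement(float(m), ref, r0)
            for m in model.means[:-1]}
    if out is not None:
        ckio.write_traces(traces, out / "fret_traces.tsv")
    return {"n_states": model.n_states,
            "state_means": [float(m) for m in model.means],
            "populations_pct": [float(x) for x in hist.populations],
            "displacements_A": disp}


def _stage_qens(p: dict, seed: int, out: Path | None) -> dict:
    cfg = simulate.QENSSimConfig(seed=seed, **p.get("sim", {}))
    spectra, truth = simulate.simulate_qens(cfg)
    if out is not None:
        ckio.write_qens_set(spectra, out / "qens")
    res = analyze_temperature_series(spectra)
    return {"ea_global_kJmol": res["arrhenius_global"].activation_energy,
            "ea_internal_kJmol": res["arrhenius_internal"].activation_energy,
            "truth_ea_global": truth["ea_global"],
            "truth_ea_internal": truth["ea_internal"]}


def _stage_sas(p: dict, seed: int, out: Path | None) -> dict:
    rng = np.random.default_rng(seed)
    q = np.asarray(p.get("q", np.linspace(0.005, 0.35, 300)))
    species = simulate.default_oligomer_models()
    basis = [simulate.debye_curve(m, q) for m in species.values()]
    weights = np.asarray(p.get("weights", [0.821, 0.037, 0.037, 0.105]))
    target = simulate.simulate_sas_mixture(
        basis, weights, noise_rel=p.get("noise_rel", 0.01), seed=rng)
    pool = basis + [simulate.debye_curve(m, q)
                    for m in simulate.decoy_pool(seed=rng)]
    sol = ga_select(pool, target, seed=rng,
                    n_max=p.get("n_max", 5),
                    generations=p.get("generations", 100),
                    iterations=p.get("iterations", 5))
    gfit = guinier_fit(target)
    if out is not None:
        ckio.write_sas_curve(target, out / "sas_target.dat")
    return {"guinier_rg_A": gfit.rg,
            "ensemble_redchi": sol.redchi,
            "class_fractions": sol.class_fractions}


def _stage_melt(p: dict, seed: int, out: Path | None) -> dict:
    conditions = p.get("conditions",
                       {"unliganded": 55.0, "agonist": 59.7})
    fits = {}
    curves = []
    for k, (name, tm) in enumerate(conditions.items()):
        cfg = simulate.MeltSimConfig(tm=tm, seed=seed + k,
                                     **p.get("sim", {}))
        curve = simulate.simulate_melt_curve(cfg, label=name)
        curves.append(curve)
        fits[name] = fit_boltzmann(curve)
    out_block = {"tm_C": {k: f.tm for k, f in fits.items()}}
    names = list(fits)
    if len(names) >= 2:
        shift, err = delta_tm(fits[names[0]], fits[names[1]])
        out_block["delta_tm_C"] = shift
        out_block["delta_tm_err"] = err
    if out is not None:
        ckio.write_melt_curves(curves, out / "melt_curves.csv")
    return out_block


_STAGE_FN = {"fret": _stage_fret, "qens": _stage_qens,
             "sas": _stage_sas, "melt": _stage_melt}


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages in order.

    A stage failure halts downstream stages; the partial report (with the
    failure recorded) is still returned.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_digest=config.digest(), seed=config.seed)
    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        log.info("running stage %s (seed %d)", stage, seed)
        try:
            block = _STAGE_FN[stage](config.params.get(stage, {}), seed, out)
        except Exception as exc:        # partial report on stage failure
            log.error("stage %s failed: %s", stage, exc)
            report.failed[stage] = str(exc)
            break
        report.stages[stage] = block
    if out is not None:
        report.to_json(out / "report.json")
        report.outputs["report"] = str(out / "report.json")
    return report


# --- acceptance comparison -------------------------------------------------

def _lookup(report: RunReport, path: str):
    node = report.stages
    for key in path.split("."):
        if not isinstance(node, dict) or key not in node:
            return None
        node = node[key]
    return node


def acceptance_check(report: RunReport, targets: list[dict]) -> list[dict]:
    """Compare report values against targets.

    Each target is {"name", "path", "value", "cmp" (eq|le|ge), "tol"}; the
    path is a dot-path into the report's stage blocks.  Missing values are
    marked unevaluable rather than failed.
    """
    rows = []
    for t in targets:
        got = _lookup(report, t["path"])
        row = {"name": t.get("name", t["path"]), "target": t["value"],
               "value": got}
        if got is None:
            row["status"] = "unevaluable"
        else:
            cmp_mode = t.get("cmp", "eq")
            tol = float(t.get("tol", 0.0))
            got_f, want = float(got), float(t["value"])
            if cmp_mode == "eq":
                ok = abs(got_f - want) <= tol
            elif cmp_mode == "le":
                ok = got_f <= want + tol
            elif cmp_mode == "ge":
                ok = got_f >= want - tol
            else:
                raise ValueError(f"unknown cmp mode {cmp_mode!r}")
            row["status"] = "pass" if ok else "fail"
        rows.append(row)
    return rows
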