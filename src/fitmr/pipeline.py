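"""Config-driven end-to-end orchestration.

Runs the full analysis graph — simulate (or read) GWAS tables, clump,
triangulate instruments, validate in a cohort, harmonise each outcome,
radial-filter, run the MR estimator suite, multivariable MR with mediation,
and a GRS association scan — writing one TSV per stage plus a run manifest.
Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import configparser
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, grs, mr, simulate, sumstats, triangulate

logger = logging.getLogger("fitmr")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Flat, diff-able configuration for one pipeline run."""

    scenario: str | None = "causal"     # synthetic scenario, or None for files
    exposure_path: str | None = None
    proxy_path: str | None = None
    outcome_paths: dict[str, str] = field(default_factory=dict)
    mediator_paths: dict[str, str] = field(default_factory=dict)
    ld_path: str | None = None
    seed: int = 0
    # instrument options
    alpha_radial: float = 0.05
    p_nominal: float = 0.05
    r2_union: float = 0.01
    p_gws: float = 5e-8
    clump_window: int = 1_000_000
    # MR options
    methods: tuple[str, ...] = ("ivw", "egger", "wmedian", "pwmedian")
    radial_filter: bool = True
    # scan options
    n_tests: int | None = None
    out_dir: str = "fitmr_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        cfg = cls()
        inp = cp["inputs"] if "inputs" in cp else {}
        cfg.scenario = inp.get("scenario") or None
        cfg.exposure_path = inp.get("exposure") or None
        cfg.proxy_path = inp.get("proxy") or None
        cfg.ld_path = inp.get("ld") or None
        if "outcomes" in cp:
            cfg.outcome_paths = dict(cp["outcomes"])
        if "mediators" in cp:
            cfg.mediator_paths = dict(cp["mediators"])
        opt = cp["options"] if "options" in cp else {}
        cfg.seed = int(opt.get("seed", cfg.seed))
        cfg.alpha_radial = float(opt.get("alpha_radial", cfg.alpha_radial))
        cfg.p_nominal = float(opt.get("p_nominal", cfg.p_nominal))
        cfg.r2_union = float(opt.get("r2_union", cfg.r2_union))
        cfg.p_gws = float(opt.get("p_gws", cfg.p_gws))
        cfg.clump_window = int(opt.get("clump_window", cfg.clump_window))
        cfg.radial_filter = opt.get("radial_filter", "yes").lower() in ("1", "yes", "true")
        if "methods" in opt:
            cfg.methods = tuple(opt["methods"].split(","))
        if "n_tests" in opt:
            cfg.n_tests = int(opt["n_tests"])
        cfg.out_dir = opt.get("out_dir", cfg.out_dir)
        return cfg

    def print_config(self) -> str:
        lines = ["[inputs]",
                 f"scenario = {self.scenario or ''}",
                 f"exposure = {self.exposure_path or ''}",
                 f"proxy = {self.proxy_path or ''}",
                 f"ld = {self.ld_path or ''}",
                 "", "[outcomes]"]
        lines += [f"{k} = {v}" for k, v in self.outcome_paths.items()]
        lines += ["", "[mediators]"]
        lines += [f"{k} = {v}" for k, v in self.mediator_paths.items()]
        lines += ["", "[options]",
                  f"seed = {self.seed}",
                  f"alpha_radial = {self.alpha_radial}",
                  f"p_nominal = {self.p_nominal}",
                  f"r2_union = {self.r2_union}",
                  f"p_gws = {self.p_gws}",
                  f"clump_window = {self.clump_window}",
                  f"radial_filter = {'yes' if self.radial_filter else 'no'}",
                  f"methods = {','.join(self.methods)}",
                  f"out_dir = {self.out_dir}"]
        if self.n_tests is not None:
            lines.append(f"n_tests = {self.n_tests}")
        return "\n".join(lines) + "\n"


def _mr_suite(h, methods, seed) -> pd.DataFrame:
    """Tidy results table over the requested estimators."""
    rows = []
    het = mr.cochran_q(h) if len(h) >= 2 else None
    egg = None
    if "egger" in methods and len(h) >= 3:
        egg = mr.egger(h)
    for name in methods:
        try:
            if name == "ivw":
                est = mr.ivw(h, model="random")
            elif name == "egger":
                est = egg
            elif name == "wmedian":
                est = mr.weighted_median(h, penalised=False, seed=seed)
            elif name == "pwmedian":
                est = mr.weighted_median(h, penalised=True, seed=seed)
            else:
                raise PipelineError("mr", "unknown_method", name)
        except mr.MrError as exc:
            logger.warning("event=method_skipped method=%s reason=%s", name, exc)
            continue
        if est is None:
            continue
        rows.append({
            "method": est.method, "n_snps": est.n_snps, "beta": est.beta,
            "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "p": est.p,
            "Q": het.Q if het else np.nan, "Q_p": het.p if het else np.nan,
            "egger_intercept": egg.intercept if egg else np.nan,
            "egger_intercept_p": egg.intercept_p if egg else np.nan,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing per-stage TSVs plus a manifest.

    Returns a dict of the in-memory stage products (tables, instruments,
    validations, MR results per outcome, MVMR results, scan results).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = simulate.spawn_rngs(config.seed, 4)
    bundle: dict = {}

    # ---- stage: inputs (simulate or read) ----------------------------------
    stage = "inputs"
    try:
        if config.scenario:
            params = simulate.scenario_params(config.scenario, seed=config.seed)
            arch = simulate.simulate_architecture(params, rngs[0])
            tables = simulate.simulate_summary_stats(arch, params, rngs[1])
            ld_ref = simulate.ld_reference(arch, params)
            cohort = simulate.simulate_cohort(arch, params, rng=rngs[2])
            exposure = tables["exposure"]
            proxy = tables["proxy"]
            outcomes = {"outcome": tables["outcome"]}
            mediators = {s.label: tables[s.label] for s in params.mediators}
            bundle["params"] = params
        else:
            if not config.exposure_path or not config.proxy_path:
                raise PipelineError(stage, "missing_input",
                                    "exposure and proxy paths are required")
            exposure = sumstats.read_summary_table(config.exposure_path,
                                                   trait_label="exposure")
            proxy = sumstats.read_summary_table(config.proxy_path,
                                                trait_label="proxy")
            outcomes, mediators = {}, {}
            for lab, p in config.outcome_paths.items():
                if not Path(p).exists():
                    raise PipelineError("harmonise", "missing_outcome_file",
                                        f"{lab}: {p}")
                outcomes[lab] = sumstats.read_summary_table(
                    p, trait_label=lab, trait_type="binary")
            for lab, p in config.mediator_paths.items():
                mediators[lab] = sumstats.read_summary_table(p, trait_label=lab)
            ld_ref = (sumstats.LdReference.from_tsv(config.ld_path)
                      if config.ld_path else sumstats.LdReference())
            cohort = None
        for lab, t in [("exposure", exposure), ("proxy", proxy),
                       *outcomes.items(), *mediators.items()]:
            sumstats.write_summary_table(t, out / f"sumstats_{lab}.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "input_error", str(exc)) from exc

    # ---- stage: clump ------------------------------------------------------
    stage = "clump"
    try:
        exposure_hits = sumstats.distance_clump(exposure, config.clump_window,
                                                config.p_gws)
        proxy_hits = sumstats.distance_clump(proxy, config.clump_window,
                                             config.p_gws)
        sumstats.write_summary_table(exposure_hits, out / "clumped_exposure.tsv")
        sumstats.write_summary_table(proxy_hits, out / "clumped_proxy.tsv")
    except Exception as exc:
        raise PipelineError(stage, "clump_error", str(exc)) from exc

    # ---- stage: triangulate ------------------------------------------------
    stage = "triangulate"
    try:
        instruments = triangulate.build_instrument_sets(
            exposure_hits, proxy_hits, exposure, ld_ref,
            alpha_radial=config.alpha_radial, p_nominal=config.p_nominal,
            r2_union=config.r2_union)
        for lab, instr in instruments.items():
            instr.to_tsv(out / f"instrument_{lab}.tsv")
        bundle["instruments"] = instruments
    except Exception as exc:
        raise PipelineError(stage, "triangulation_error", str(exc)) from exc

    # ---- stage: validate ---------------------------------------------------
    stage = "validate"
    selected_label = "I4" if len(instruments["I4"]) else "I1"
    if cohort is not None:
        try:
            validations = [triangulate.validate_instrument(instruments[lab], cohort)
                           for lab in ("I1", "I2", "I3", "I4")
                           if len(instruments[lab])]
            selected_label = triangulate.select_instrument(validations)
            pd.DataFrame([{
                "label": v.label, "r_squared": v.r_squared, "p": v.p,
                "n_members": v.n_members,
                **{f"decile_{d + 1}": m for d, m in enumerate(v.decile_means)},
            } for v in validations]).to_csv(out / "validation.tsv", sep="\t",
                                            index=False)
            bundle["validations"] = validations
        except Exception as exc:
            raise PipelineError(stage, "validation_error", str(exc)) from exc
    instrument = instruments[selected_label]
    bundle["selected"] = selected_label

    # ---- stage: harmonise + MR per outcome --------------------------------
    mr_frames = []
    mvmr_rows = []
    for lab, outcome_table in outcomes.items():
        stage = "harmonise"
        try:
            instr_table = exposure.subset(instrument.variant_ids)
            h = sumstats.harmonise_pair(instr_table, outcome_table,
                                        ld_ref=ld_ref, use_proxies=True)
        except Exception as exc:
            raise PipelineError(stage, "harmonise_error", f"{lab}: {exc}") from exc
        stage = "mr"
        try:
            if config.radial_filter and len(h) >= 3:
                h_f, _ = mr.radial_outlier_filter(h, alpha=config.alpha_radial)
            else:
                h_f = h
            for filtered, hh in (("no", h), ("yes", h_f)):
                frame = _mr_suite(hh, config.methods, config.seed)
                frame.insert(0, "radial_filtered", filtered)
                frame.insert(0, "outcome", lab)
                mr_frames.append(frame)
        except Exception as exc:
            raise PipelineError(stage, "mr_error", f"{lab}: {exc}") from exc

        if mediators:
            stage = "mvmr"
            try:
                hm = h_f
                for med in mediators.values():
                    hm = sumstats.add_mediator(hm, med)
                res = mr.mvmr(hm)
                for name, b, s, p in zip(res.exposures, res.beta, res.se, res.p):
                    mvmr_rows.append({
                        "outcome": lab, "exposure": name, "beta": b, "se": s,
                        "p": p, "n_snps": res.n_snps,
                        "mediation_percent": res.mediation_percent_reported,
                    })
            except Exception as exc:
                raise PipelineError(stage, "mvmr_error", f"{lab}: {exc}") from exc

    if mr_frames:
        pd.concat(mr_frames, ignore_index=True).to_csv(
            out / "mr_results.tsv", sep="\t", index=False)
        bundle["mr_results"] = pd.concat(mr_frames, ignore_index=True)
    if mvmr_rows:
        pd.DataFrame(mvmr_rows).to_csv(out / "mvmr_results.tsv", sep="\t",
                                       index=False)
        bundle["mvmr_results"] = pd.DataFrame(mvmr_rows)

    # ---- stage: GRS scan ---------------------------------------------------
    if cohort is not None:
        stage = "grs_scan"
        try:
            score = grs.compute_grs(cohort, instrument)
            trait_cols = [c for c in cohort.phenotypes.columns
                          if c not in ("exposure", "outcome")]
            if trait_cols:
                scan = grs.association_scan(score, cohort.phenotypes[trait_cols],
                                            cohort.covariates,
                                            n_tests=config.n_tests)
                scan.to_csv(out / "grs_scan.tsv", sep="\t", index=False)
                bundle["scan"] = scan
        except Exception as exc:
            raise PipelineError(stage, "scan_error", str(exc)) from exc

    manifest = {
        "fitmr_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "selected_instrument": selected_label,
        "config": config.print_config(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle
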