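"""End-to-end analysis pipeline and publication-style report tables.

``run_pipeline`` executes the full best-worst workflow on one dataset —
counting scores, pooled fit, mixed-logit fit with population shares of
preference, latent-class sweep and fit, posterior profiling — and writes
every stage as plain CSV (a rounded presentation table plus a
full-precision companion) together with a machine-readable settings echo
sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import BWDesign
from .latent import LatentClassMaxDiffModel, class_sweep, profile_classes
from .maxdiff import MaxDiffModel
from .mixed import MixedMaxDiffModel
from .panel import read_panel
from .scores import ScoreTable
from .simulate import load_study_fixture

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Settings for one pipeline run (YAML-serializable)."""

    design: str = "fixture"          # design JSON path, or "fixture"
    panel: str = "fixture"           # response CSV path, or "fixture"
    covariates: str | None = None    # covariate CSV path (fixture: bundled)
    outdir: str = "bws_report"
    reference: str = "O9"
    mixed_draws: int = 500
    mixed_seed: int = 1
    lc_classes: int = 3
    lc_min: int = 2
    lc_max: int = 5
    lc_starts: int = 10
    lc_seed: int = 1
    share_draws: int = 10000
    share_seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(cfg: RunConfig):
    if cfg.panel == "fixture" or cfg.design == "fixture":
        design, panel, cov = load_study_fixture()
        return design, panel, cov
    design = BWDesign.from_json(cfg.design)
    panel = read_panel(cfg.panel, design, covariates_path=cfg.covariates)
    return design, panel, panel.covariates


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, lineterminator="\n", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run scores -> pooled -> mixed -> LC sweep -> LC fit -> profile.

    Returns a dict of output paths; every estimation stage failure raises
    with a stage-tagged message.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    design, panel, cov = _load_inputs(config)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # -- counting scores -------------------------------------------------
    def _scores():
        st = ScoreTable.from_panel(panel)
        disp = st.display()
        _write(disp, out / "scores.csv", index_label="option")
        _write(st.table, out / "scores_full.csv", index_label="option")
        return st

    stage("scores", _scores)
    paths["scores"] = str(out / "scores.csv")

    # -- pooled ----------------------------------------------------------
    def _pooled():
        res = MaxDiffModel(panel, reference=config.reference).fit()
        with open(out / "pooled.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=1)
            fh.write("\n")
        return res

    pooled = stage("pooled", _pooled)
    paths["pooled"] = str(out / "pooled.json")

    # -- mixed logit -----------------------------------------------------
    def _mixed():
        res = MixedMaxDiffModel(
            panel, reference=config.reference, n_draws=config.mixed_draws,
            seed=config.mixed_seed).fit(start=None)
        shares = res.population_shares(n_draws=config.share_draws,
                                       seed=config.share_seed)
        tab = res.summary()
        tab["sp_mean"] = shares["mean"]
        tab["sp_sd"] = shares["sd"]
        _write(tab.round(4), out / "mixed_estimates.csv", index_label="option")
        _write(tab, out / "mixed_estimates_full.csv", index_label="option")
        with open(out / "mixed.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=1)
            fh.write("\n")
        return res

    stage("mixed", _mixed)
    paths["mixed"] = str(out / "mixed_estimates.csv")

    # -- latent class sweep + fit ---------------------------------------
    def _sweep():
        tab = class_sweep(panel, config.lc_min, config.lc_max,
                          n_starts=config.lc_starts, seed=config.lc_seed,
                          reference=config.reference)
        _write(tab.round(2), out / "class_sweep.csv", index=False)
        _write(tab, out / "class_sweep_full.csv", index=False)
        return tab

    stage("class_sweep", _sweep)
    paths["class_sweep"] = str(out / "class_sweep.csv")

    def _lc():
        res = LatentClassMaxDiffModel(
            panel, config.lc_classes, reference=config.reference).fit(
            n_starts=config.lc_starts, seed=config.lc_seed)
        sp = res.class_shares_of_preference()
        rows = []
        for cls in res.class_beta.index:
            for opt in res.class_beta.columns:
                rows.append({
                    "class": cls, "share": res.class_shares[cls], "option": opt,
                    "coef": res.class_beta.loc[cls, opt],
                    "std_err": None if res.class_bse is None
                    else res.class_bse.loc[cls, opt],
                    "sp": sp.loc[cls, opt],
                })
        tab = pd.DataFrame(rows)
        _write(tab.round(4), out / "latent_class.csv", index=False)
        _write(tab, out / "latent_class_full.csv", index=False)
        with open(out / "lc.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=1)
            fh.write("\n")
        return res

    lc = stage("latent_class", _lc)
    paths["latent_class"] = str(out / "latent_class.csv")

    # -- covariate profiles ---------------------------------------------
    if cov is not None and len(cov.columns):
        def _profile():
            tab = profile_classes(lc.assign(), cov)
            _write(tab.round(1), out / "class_profiles.csv")
            _write(tab, out / "class_profiles_full.csv")
            return tab

        stage("profile", _profile)
        paths["profile"] = str(out / "class_profiles.csv")

    echo = {"bwskit_version": __version__, "config": asdict(config),
            "pooled_loglik": pooled.llf, "lc_loglik": lc.llf}
    with open(out / "settings.json", "w") as fh:
        json.dump(echo, fh, indent=1, default=str)
        fh.write("\n")
    paths["settings"] = str(out / "settings.json")
    return paths
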