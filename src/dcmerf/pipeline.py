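"""End-to-end analysis pipeline.

simulate -> per-subject variational inversions -> per-group PEBs (drug
effect) -> third-level PEB-of-PEBs (group effects and drug x group
interactions) -> GABA-covariate model comparison -> report.

Group analyses run on deviant-condition posteriors (the analysis focuses
on the response to deviant events); standard-condition posteriors are
fitted and stored but only enter group models when explicitly requested.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bmr import compare_evidence
from .cohort import CohortSpec, SyntheticCohort, generate_cohort
from .erf import GROUPS
from .inversion import ERFModel, InversionSettings, invert
from .observation import summarize_correlations
from .params import GaussianBelief, build_parameter_priors, DEFAULT_FREE_CLASSES
from .peb import (DesignMatrix, PEBModel, PEBSettings, fit_peb, peb_of_pebs,
                  threshold_effects)

log = logging.getLogger("dcmerf")


@dataclass
class RunConfig:
    outdir: str = "dcmerf_run"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    free_classes: tuple = DEFAULT_FREE_CLASSES
    inversion: InversionSettings = field(default_factory=InversionSettings)
    peb: PEBSettings = field(default_factory=PEBSettings)
    pp_threshold: float = 0.95
    #: condition whose posteriors feed the group analyses
    analysis_condition: str = "deviant"
    jobs: int = 1
    resume: bool = True

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        if isinstance(self.inversion, dict):
            self.inversion = InversionSettings(**self.inversion)
        if isinstance(self.peb, dict):
            self.peb = PEBSettings(**self.peb)
        self.free_classes = tuple(self.free_classes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _plain(x):
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.integer, np.floating)):
        return float(x)
    return x


class PipelineRun:
    """Stateful run directory: cohort, posterior store, analysis outputs."""

    def __init__(self, config: RunConfig):
        self.config = config
        config.cohort = CohortSpec(**{**asdict(config.cohort),
                                      "seed": config.seed})
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cohort: SyntheticCohort | None = None
        self.beliefs: dict = {}
        self.fit_table: pd.DataFrame | None = None
        self.results: dict = {}

    # -- stages --------------------------------------------------------------

    def simulate(self) -> SyntheticCohort:
        t0 = time.time()
        self.cohort = generate_cohort(self.config.cohort)
        log.info("simulate: %d subjects, fidelity=%s (%.1fs)",
                 len(self.cohort.subjects), self.config.cohort.fidelity,
                 time.time() - t0)
        return self.cohort

    def fit(self) -> pd.DataFrame:
        """Invert every subject x session x condition dataset (cached)."""
        if self.cohort is None:
            self.simulate()
        cohort = self.cohort
        if cohort.spec.fidelity == "posterior":
            # first-level posteriors are given directly; fits are a no-op
            self.beliefs = {(s, sess, "deviant"): b
                            for (s, sess), b in cohort.beliefs.items()}
            self.fit_table = pd.DataFrame(
                [{"subject": s, "session": sess, "condition": "deviant",
                  "F": b.F, "converged": True, "median_r": np.nan,
                  "cached": True}
                 for (s, sess, _), b in self.beliefs.items()]
            )
            return self.fit_table
        prior = build_parameter_priors(cohort.net, self.config.free_classes)
        model = ERFModel(cohort.net)
        store = self.outdir / "posteriors.h5"
        rows = []
        n_refit = 0
        pending = []  # cache misses, inverted (possibly in parallel) below
        cached = {}
        for ds in cohort.datasets:
            key = f"{ds.subject}/{ds.session}/{ds.condition}"
            h = _fit_hash(ds.erf, self.config)
            post = _load_cached(store, key, h) if self.config.resume else None
            if post is None:
                pending.append((ds, key, h))
            else:
                cached[key] = post
        if pending:
            if self.config.jobs > 1:
                from joblib import Parallel, delayed

                fits = Parallel(n_jobs=self.config.jobs)(
                    delayed(invert)(ds, model, prior, self.config.inversion)
                    for ds, _, _ in pending)
            else:
                fits = [invert(ds, model, prior, self.config.inversion)
                        for ds, _, _ in pending]
            for (ds, key, h), post in zip(pending, fits):
                post.meta["fit_hash"] = h
                _store_posterior(store, key, post)
                cached[key] = post
                n_refit += 1
        for ds in cohort.datasets:
            key = f"{ds.subject}/{ds.session}/{ds.condition}"
            post = cached[key]
            self.beliefs[(ds.subject, ds.session, ds.condition)] = post
            fit = post.meta.get("fit") or {}
            rows.append({
                "subject": ds.subject, "session": ds.session,
                "condition": ds.condition, "F": post.F,
                "converged": post.meta.get("converged", False),
                "median_r": fit.get("median_r"),
                "cached": post.meta.get("cached", False),
            })
        self.fit_table = pd.DataFrame(rows)
        log.info("fit: %d posteriors (%d refit, %d cached)",
                 len(rows), n_refit, len(rows) - n_refit)
        return self.fit_table

    def _analysis_beliefs(self):
        cond = self.config.analysis_condition
        out = {}
        missing = []
        for _, row in self.cohort.subjects.iterrows():
            for sess in self.cohort.spec.sessions:
                b = self.beliefs.get((row["subject"], sess, cond))
                if b is None:
                    missing.append((row["subject"], sess))
                else:
                    out[(row["subject"], sess)] = b
        if missing:
            raise RuntimeError(f"missing posteriors for {missing}")
        return out

    def peb(self) -> dict:
        """Per-group PEBs with a drug column, then a third-level
        PEB-of-PEBs comparing groups."""
        if not self.beliefs:
            self.fit()
        beliefs = self._analysis_beliefs()
        prior = _first_level_prior(self.cohort, self.config)
        groups = [g for g in GROUPS if g in set(self.cohort.subjects["group"])]
        group_pebs = {}
        for g in groups:
            subj = self.cohort.subjects.query("group == @g")["subject"]
            keys = [(s, sess) for s in subj for sess in self.cohort.spec.sessions]
            posts = [beliefs[k] for k in keys]
            X = DesignMatrix.mean_only(len(keys)).add_contrast(
                "drug", [1.0 if sess == "tiagabine" else -1.0 for _, sess in keys]
            )
            group_pebs[g] = fit_peb(posts, X, prior, self.config.peb)
        X2 = DesignMatrix.mean_only(len(groups))
        if set(groups) == set(GROUPS):
            X2 = (X2
                  .add_contrast("ctrl-pat",
                                [1.0 if g == "control" else -1.0 for g in groups])
                  .add_contrast("PSP-bvFTD",
                                [{"PSP": 1.0, "bvFTD": -1.0}.get(g, 0.0)
                                 for g in groups]))
        third = peb_of_pebs([group_pebs[g] for g in groups], X2, self.config.peb)
        self.results["group_pebs"] = group_pebs
        self.results["third_level"] = third
        self.results["third_level_significant"] = threshold_effects(
            third, self.config.pp_threshold)
        return self.results

    def gaba(self, shuffle_seed: int | None = None) -> dict:
        """Free-energy comparison of the between-subject model with vs
        without the GABA covariate, plus GABA interaction effects.

        ``shuffle_seed`` permutes GABA across subjects first (a sanity
        check that should destroy the covariate's contribution)."""
        if not self.beliefs:
            self.fit()
        subjects = self.cohort.subjects
        if subjects["gaba"].isna().any():
            log.warning("gaba: covariate missing for some subjects; skipped")
            return {"skipped": True}
        beliefs = self._analysis_beliefs()
        prior = _first_level_prior(self.cohort, self.config)
        # the covariate analysis concerns the GABAergic synapses
        gaba_names = [n for n in prior.names
                      if n.startswith(("tonic:", "phasic:"))]
        prior = prior.subset(gaba_names)
        keys = [(s, sess) for s in subjects["subject"]
                for sess in self.cohort.spec.sessions]
        posts = [beliefs[k].subset(gaba_names) for k in keys]
        gaba = subjects.set_index("subject")["gaba"]
        if shuffle_seed is not None:
            rng = np.random.default_rng(shuffle_seed)
            gaba = pd.Series(rng.permutation(gaba.to_numpy()), index=gaba.index)
        group = subjects.set_index("subject")["group"]
        drug = [1.0 if sess == "tiagabine" else -1.0 for _, sess in keys]
        ctrl = [1.0 if group[s] == "control" else -1.0 for s, _ in keys]
        pvb = [{"PSP": 1.0, "bvFTD": -1.0}.get(group[s], 0.0) for s, _ in keys]
        X0 = (DesignMatrix.mean_only(len(keys))
              .add_contrast("ctrl-pat", ctrl)
              .add_contrast("PSP-bvFTD", pvb)
              .add_contrast("drug", drug))
        Xg = X0.add_covariate("gaba", [gaba[s] for s, _ in keys])
        # interactions with group and drug are explored in a separate model
        Xi = (Xg.add_interaction("gaba", "drug")
                .add_interaction("gaba", "PSP-bvFTD"))
        peb0 = fit_peb(posts, X0, prior, self.config.peb)
        pebg = fit_peb(posts, Xg, prior, self.config.peb)
        pebi = fit_peb(posts, Xi, prior, self.config.peb)
        comparison = compare_evidence([peb0.F, pebg.F],
                                      ["without GABA", "with GABA"])
        out = {
            "comparison": comparison,
            "delta_F": pebg.F - peb0.F,
            "peb_without": peb0,
            "peb_with": pebg,
            "peb_interactions": pebi,
            "gaba_effects": pebi.effect_table().query(
                "effect in ('gaba', 'gabaxdrug', 'gabaxPSP-bvFTD')"
            ).reset_index(drop=True),
        }
        if shuffle_seed is None:
            self.results["gaba"] = out
        return out

    def report(self) -> dict:
        """Write the CSV/JSON report bundle; regeneration from the stored
        results is deterministic."""
        out = self.outdir
        summary = {
            "config_hash": self.config.hash(),
            "seed": self.config.seed,
            "analyses": [],
            "partial": False,
        }
        if self.fit_table is not None:
            self.fit_table.to_csv(out / "fit_table.csv", index=False)
            rs = [r for r in self.fit_table["median_r"] if pd.notna(r)]
            summary["fit"] = summarize_correlations(rs)
            summary["analyses"].append("fit")
        if "third_level" in self.results:
            for g, m in self.results["group_pebs"].items():
                m.effect_table().to_csv(out / f"peb_{g}.csv", index=False)
            self.results["third_level"].effect_table().to_csv(
                out / "third_level.csv", index=False)
            self.results["third_level_significant"].to_csv(
                out / "third_level_significant.csv", index=False)
            summary["analyses"].append("peb")
        if "gaba" in self.results:
            g = self.results["gaba"]
            g["gaba_effects"].to_csv(out / "gaba_effects.csv", index=False)
            with open(out / "gaba_comparison.json", "w") as fh:
                json.dump({"comparison": g["comparison"],
                           "delta_F": g["delta_F"]}, fh, indent=2)
            summary["analyses"].append("gaba")
        summary["partial"] = len(summary["analyses"]) < 3
        with open(out / "run.json", "w") as fh:
            json.dump(_plain(summary), fh, indent=2)
        try:
            self._figures()
        except Exception as exc:  # figures are a convenience, never fatal
            log.warning("report figures skipped: %s", exc)
        return summary

    def _figures(self) -> None:
        """Kernel-density summary of fit correlations and a Pp effect map."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.fit_table is not None:
            rs = np.array([r for r in self.fit_table["median_r"]
                           if pd.notna(r)])
            if rs.size >= 3 and np.ptp(rs) > 0:
                from scipy.stats import gaussian_kde

                fig, ax = plt.subplots(figsize=(4, 3))
                grid = np.linspace(max(-1, rs.min() - 0.1),
                                   min(1, rs.max() + 0.1), 200)
                ax.fill_between(grid, gaussian_kde(rs)(grid), alpha=0.4)
                ax.axvline(np.median(rs), color="r")
                ax.set_xlabel("observed vs modelled ERF correlation")
                ax.set_ylabel("density")
                fig.tight_layout()
                fig.savefig(self.outdir / "fit_correlations.png", dpi=120)
                plt.close(fig)
        if "third_level" in self.results:
            third = self.results["third_level"]
            fig, ax = plt.subplots(figsize=(7, 3.5))
            im = ax.imshow(third.Pp, vmin=0, vmax=1, cmap="viridis",
                           aspect="auto")
            ax.set_yticks(range(len(third.columns)), third.columns)
            ax.set_xticks(range(len(third.parameters)), third.parameters,
                          rotation=90, fontsize=6)
            fig.colorbar(im, label="posterior probability")
            fig.tight_layout()
            fig.savefig(self.outdir / "effect_map.png", dpi=120)
            plt.close(fig)

    def score_correlation(self, scores: dict, parameter: str,
                          session: str = "placebo") -> dict:
        """Hook for relating an optional per-subject clinical score to a
        posterior parameter estimate (Pearson r over subjects with a
        score); makes no claim beyond the correlation it reports."""
        from .observation import pearson

        xs, ys = [], []
        cond = self.config.analysis_condition
        for subj, score in scores.items():
            b = self.beliefs.get((subj, session, cond))
            if b is None or score is None:
                continue
            xs.append(float(score))
            ys.append(float(b.mean[b.index(parameter)]))
        r = pearson(np.array(xs), np.array(ys)) if len(xs) >= 3 else None
        return {"parameter": parameter, "n": len(xs), "r": r}

    def all(self) -> dict:
        self.simulate()
        self.fit()
        self.peb()
        self.gaba()
        return self.report()


def _first_level_prior(cohort: SyntheticCohort, config: RunConfig) -> GaussianBelief:
    if cohort.spec.fidelity == "posterior":
        return cohort.prior
    return build_parameter_priors(cohort.net, config.free_classes)


# ---------------------------------------------------------------------------
# posterior store

def _fit_hash(erf: np.ndarray, config: RunConfig) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(erf).tobytes())
    h.update(json.dumps(_plain(asdict(config.inversion)),
                        sort_keys=True).encode())
    h.update(",".join(config.free_classes).encode())
    return h.hexdigest()[:16]


def _store_posterior(path, key: str, post: GaussianBelief) -> None:
    with h5py.File(path, "a") as fh:
        if key in fh:
            del fh[key]
        grp = fh.create_group(key)
        post.to_hdf5(grp)
        grp.attrs["fit_hash"] = post.meta["fit_hash"]
        grp.attrs["converged"] = bool(post.meta.get("converged", False))
        fit = post.meta.get("fit") or {}
        if fit.get("median_r") is not None:
            grp.attrs["median_r"] = fit["median_r"]


def _load_cached(path, key: str, fit_hash: str) -> GaussianBelief | None:
    path = Path(path)
    if not path.exists():
        return None
    with h5py.File(path, "r") as fh:
        if key not in fh or fh[key].attrs.get("fit_hash") != fit_hash:
            return None
        post = GaussianBelief.from_hdf5(fh[key])
        post.meta["converged"] = bool(fh[key].attrs.get("converged", False))
        if "median_r" in fh[key].attrs:
            post.meta["fit"] = {"median_r": float(fh[key].attrs["median_r"])}
        post.meta["cached"] = True
        return post
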