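"""End-to-end observed-vs-expected analysis as a model/results pair.

``ExcessIncidenceModel`` holds the three study inputs (cohort, events,
disease definitions) and a :class:`~excessrisk.config.RunConfig`.  Its
``fit()`` runs the full pipeline -- per-disease Weibull fits with left
truncation, Poisson-Binomial expected counts with QC, outlier exclusion and
the through-origin regression -- and returns ``ExcessIncidenceResults`` with
the per-disease table, the headline excess-risk multiplier for both observed
series, subgroup slopes, chapter aggregation, a text summary and a
Fig.-style scatter plot.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .comparison import DiseasePoint, SlopeEstimate, chapter_ratios, exclude_outliers, fit_through_origin
from .config import RunConfig
from .design import design_matrix
from .expectation import (
    ExpectedCount,
    ObservedCount,
    build_fit_records,
    build_risk_set,
    disease_table_row,
    expected_count,
    observed_counts,
    qc_filter,
)
from .weibull import DiseaseModel, WeibullIncidenceModel

__all__ = ["ExcessIncidenceModel", "ExcessIncidenceResults"]


class ExcessIncidenceModel:
    """Observed-vs-expected excess incidence analysis for one cohort.

    Parameters
    ----------
    cohort, events, diseases : DataFrame
        The study inputs (see :mod:`excessrisk.io` for schemas).  To analyse
        one sex separately (the study convention), pass the restricted
        cohort.
    config : RunConfig, optional
    models : list of DiseaseModel, optional
        Pre-fitted per-disease models; when given, fitting is skipped and
        the pipeline only recomputes expectations and comparisons.
    """

    def __init__(self, cohort: pd.DataFrame, events: pd.DataFrame, diseases: pd.DataFrame,
                 config: RunConfig | None = None, models: list[DiseaseModel] | None = None):
        self.cohort = cohort.reset_index(drop=True)
        self.events = events.reset_index(drop=True)
        self.diseases = diseases.reset_index(drop=True)
        self.config = config or RunConfig()
        self.chapter_map: dict[str, str] = dict(zip(diseases["disease_id"], diseases["chapter"]))
        unknown = set(self.events["disease_id"].unique()) - set(self.chapter_map)
        if unknown:
            raise KeyError(f"event table references undefined diseases: {sorted(unknown)[:5]}")
        self._models = {m.disease_id: m for m in models} if models else None

    @classmethod
    def from_csv(cls, cohort_path, events_path, diseases_path, config=None, models_path=None):
        from . import io as _io

        models = _io.read_models(models_path) if models_path else None
        return cls(_io.read_cohort(cohort_path), _io.read_events(events_path),
                   _io.read_disease_definitions(diseases_path), config=config, models=models)

    # ------------------------------------------------------------------

    def fit_disease(self, disease_id: str) -> DiseaseModel | None:
        """Fit one disease's Weibull incidence model (None if too few events)."""
        cfg = self.config
        rec = build_fit_records(self.cohort, self.events, disease_id, self.chapter_map, cfg)
        n_events = int(rec["event"].sum())
        if n_events < cfg.min_events:
            return None
        model = WeibullIncidenceModel.from_dataframe(
            rec, factors=cfg.factors, exit_col="end_age",
            disease_id=disease_id, chapter=self.chapter_map[disease_id])
        try:
            return model.fit().as_disease_model()
        except (ValueError, np.linalg.LinAlgError) as err:  # flagged, not fatal
            warnings.warn(f"fit failed for {disease_id}: {err}", RuntimeWarning)
            return None

    def fit(self, verbose: bool = False) -> "ExcessIncidenceResults":
        cfg = self.config
        models: dict[str, DiseaseModel] = {}
        expectations: dict[str, ExpectedCount] = {}
        observations: dict[str, ObservedCount] = {}
        rows = []
        for disease_id in self.diseases["disease_id"]:
            model = (self._models.get(disease_id) if self._models is not None
                     else self.fit_disease(disease_id))
            if model is None:
                if verbose:
                    print(f"[fit] {disease_id}: skipped (too few events or fit failure)")
                continue
            risk = build_risk_set(self.cohort, self.events, disease_id, cfg)
            X, _ = design_matrix(risk, cfg.factors) if cfg.factors else (None, None)
            ec = expected_count(model, risk, X)
            obs = observed_counts(self.events, self.cohort, disease_id, self.chapter_map,
                                  risk_ids=ec.individual_ids)
            qc = qc_filter(model, ec, obs, cfg)
            models[disease_id] = model
            expectations[disease_id] = ec
            observations[disease_id] = obs
            rows.append(disease_table_row(model, ec, obs, qc))
            if verbose:
                status = "ok" if qc.passed else "EXCLUDED " + ",".join(qc.reasons)
                print(f"[fit] {disease_id}: E={ec.expected:.1f} obs={obs.n_all} "
                      f"fic={obs.n_fic} qc={status}")
        table = pd.DataFrame(rows)
        return ExcessIncidenceResults(self, models, expectations, observations, table)


class ExcessIncidenceResults:
    """Fitted pipeline: per-disease table, slopes, subgroups, chapters, plots."""

    def __init__(self, model: ExcessIncidenceModel, models, expectations, observations, table):
        self.model = model
        self.config = model.config
        self.disease_models = models
        self.expectations = expectations
        self.observations = observations
        self.disease_table = table
        self.points = self._build_points()
        qc_pass = set(table.loc[table["qc_pass"], "disease_id"]) if len(table) else set()
        self._qc_points = [pt for pt in self.points if pt.disease_id in qc_pass]
        exclude_outliers(self._qc_points, self.config.qc.outlier_sd)

    def _build_points(self) -> list[DiseasePoint]:
        pts = []
        for disease_id, ec in self.expectations.items():
            obs = self.observations[disease_id]
            pts.append(DiseasePoint(
                disease_id=disease_id,
                chapter=self.model.chapter_map[disease_id],
                expected=ec.expected,
                sd_expected=float(np.sqrt(ec.variance)),
                observed_all=obs.n_all,
                observed_fic=obs.n_fic,
            ))
        return pts

    # -- headline results ----------------------------------------------

    @property
    def included_points(self) -> list[DiseasePoint]:
        return [pt for pt in self._qc_points if pt.included]

    def slope(self, y_series: str | None = None) -> SlopeEstimate:
        """Through-origin excess multiplier for the chosen observed series."""
        y = y_series or self.config.y_series
        return fit_through_origin(self._qc_points, y_series=y, z=self.config.qc.z)

    def chapter_table(self, y_series: str | None = None) -> pd.DataFrame:
        return chapter_ratios(self._qc_points, y_series=y_series or self.config.y_series)

    def points_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "disease_id": pt.disease_id, "chapter": pt.chapter,
            "expected": pt.expected, "sd_expected": pt.sd_expected,
            "observed_all": pt.observed_all, "observed_fic": pt.observed_fic,
            "included": pt.included, "z_fic": pt.z_fic,
            "exclusion_reason": pt.exclusion_reason,
        } for pt in self._qc_points])

    # -- subgroup slopes -------------------------------------------------

    def subgroup_slopes(self, groups: dict[str, str | None] | None = None,
                        y_series: str | None = None) -> pd.DataFrame:
        """Recompute expected and observed counts within each subgroup and refit.

        Groups are pandas query strings over the cohort table (None =
        everyone); expected counts are sums of the fitted per-individual
        probabilities over group members only, observed counts are restricted
        to members, and the outlier rule and through-origin fit are re-applied
        per group.  Empty groups and groups with too few points are skipped
        with a warning.
        """
        groups = groups if groups is not None else self.config.subgroups
        y = y_series or self.config.y_series
        cohort = self.model.cohort
        rows = []
        for name, query in groups.items():
            member_ids = (cohort if query is None else cohort.query(query))["individual_id"]
            member_ids = set(member_ids.to_numpy().tolist())
            if not member_ids:
                warnings.warn(f"subgroup {name!r} selects no individuals; skipped")
                continue
            pts = []
            for disease_id, ec in self.expectations.items():
                if not self.disease_table.set_index("disease_id").loc[disease_id, "qc_pass"]:
                    continue
                mask = np.isin(ec.individual_ids, list(member_ids))
                if not mask.any():
                    continue
                p = ec.p[mask]
                obs = observed_counts(self.model.events, cohort, disease_id,
                                      self.model.chapter_map,
                                      risk_ids=ec.individual_ids[mask])
                pts.append(DiseasePoint(
                    disease_id=disease_id, chapter=self.model.chapter_map[disease_id],
                    expected=float(p.sum()), sd_expected=float(np.sqrt((p * (1 - p)).sum())),
                    observed_all=obs.n_all, observed_fic=obs.n_fic))
            exclude_outliers(pts, self.config.qc.outlier_sd)
            kept = [pt for pt in pts if pt.included]
            if len(kept) < self.config.min_points:
                warnings.warn(f"subgroup {name!r}: only {len(kept)} usable points; skipped")
                continue
            est = fit_through_origin(pts, y_series=y, z=self.config.qc.z)
            rows.append({"group": name, "coef": est.coef, "ci_low": est.ci95[0],
                         "ci_high": est.ci95[1], "r_squared": est.r_squared,
                         "n_points": est.n_points})
        return pd.DataFrame(rows, columns=["group", "coef", "ci_low", "ci_high",
                                           "r_squared", "n_points"])

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        lines = [
            "Excess incidence analysis (observed vs expected disease counts)",
            f"diseases fitted: {len(self.points)}  "
            f"QC-passed: {len(self._qc_points)}  "
            f"retained after {self.config.qc.outlier_sd:g}-sd rule: {len(self.included_points)}",
        ]
        rows = []
        for series in ("all", "fic"):
            try:
                est = self.slope(series)
            except ValueError:
                continue
            rows.append([series, f"{est.coef:.3f}",
                         f"[{est.ci95[0]:.3f}, {est.ci95[1]:.3f}]",
                         f"{est.r_squared:.3f}", f"{est.n_points}"])
        if rows:
            lines.append(str(SimpleTable(
                rows, headers=["series", "slope", "95% CI", "R^2", "n"],
                title="Through-origin fit of observed on expected counts")))
        return "\n".join(lines)

    def plot_observed_expected(self, ax=None, y_series: str | None = None):
        """Scatter of observed vs expected counts with CIs and the fit band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pts = self._qc_points
        exp = np.array([pt.expected for pt in pts])
        sd = np.array([pt.sd_expected for pt in pts])
        z = self.config.qc.z
        ax.errorbar(exp, [pt.observed_all for pt in pts], xerr=z * sd, fmt="o", ms=4,
                    color="black", lw=0.8, label="all cases")
        ax.plot(exp, [pt.observed_fic for pt in pts], "o", ms=4, mfc="none",
                color="tab:blue", label="first in chapter")
        try:
            est = self.slope(y_series)
            xs = np.linspace(0.0, max(exp.max() * 1.05, 1.0), 100)
            yhat, lo, hi = est.predict_interval(xs)
            ax.plot(xs, yhat, "-", color="tab:red",
                    label=f"slope {est.coef:.2f} [{est.ci95[0]:.2f}, {est.ci95[1]:.2f}]")
            ax.fill_between(xs, lo, hi, color="tab:red", alpha=0.15, lw=0)
        except ValueError:
            pass
        lim = ax.get_xlim()[1]
        ax.plot([0, lim], [0, lim], ":", color="grey", lw=1, label="observed = expected")
        ax.set_xlabel("Expected number of cases")
        ax.set_ylabel("Observed number of cases")
        ax.legend(frameon=False)
        return ax

    def save(self, outdir) -> dict[str, str]:
        """Write results tables and the scatter plot to a directory."""
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        self.disease_table.to_csv(outdir / "diseases_results.csv", index=False)
        paths["diseases_results"] = str(outdir / "diseases_results.csv")
        self.points_table().to_csv(outdir / "comparison_points.csv", index=False)
        paths["comparison_points"] = str(outdir / "comparison_points.csv")
        slopes = self.subgroup_slopes()
        slopes.to_csv(outdir / "slopes.csv", index=False)
        paths["slopes"] = str(outdir / "slopes.csv")
        self.chapter_table().to_csv(outdir / "chapters.csv", index=False)
        paths["chapters"] = str(outdir / "chapters.csv")
        try:
            ax = self.plot_observed_expected()
            ax.figure.savefig(outdir / "observed_vs_expected.png", dpi=120,
                              bbox_inches="tight")
            plt.close(ax.figure)
            paths["figure"] = str(outdir / "observed_vs_expected.png")
        except ValueError:
            pass
        return paths
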