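"""The three calibration studies on synthetic data.

1. ``exp_within_matrix``: PLSR, SVM and SSA-BP calibrated and tested inside
   the D. officinale-like matrix (preprocessing-chain search, CARS wavelength
   selection, SPXY 7:3 split).
2. ``exp_cross_matrix``: the same D. officinale-calibrated models predict
   fixed 30-sample Saffron-like and Curcuma-like test sets using the base
   wavelength selection — the calibration-transfer stress test.
3. ``exp_augmentation``: target-matrix samples are added to the training set
   in groups of five (low to high concentration) with optional secondary
   CARS screening per step; SVM serves the Saffron-like target and PLSR the
   Curcuma-like target.

Everything is reproducible from the config seed.  Preprocessing contexts are
always fitted on the training samples only, so test spectra never contribute
set-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics
from .models import (
    SSAConfig,
    choose_lv_by_cv,
    plsr_fit,
    pls_rmsecv,
    ssa_bp_fit,
    svr_fit,
    svr_grid_cv,
)
from .models.neural import init_bp, bp_train
from .preprocess import apply_chain, msc, parse_chain
from .select import ensemble_cars, secondary_screen
from .split import augmentation_schedule, random_test_select, spxy_split
from .synth import (
    MatrixProfile,
    SpectralDataset,
    StudyDesign,
    default_design,
    default_profiles,
    simulate_study,
)

__all__ = [
    "CHAIN_SEARCH_SPACE",
    "ExperimentConfig",
    "exp_within_matrix",
    "exp_cross_matrix",
    "exp_augmentation",
]

#: The preprocessing chains reported by the source studies.
CHAIN_SEARCH_SPACE: tuple[str, ...] = (
    "airPLS+SG+MSC",
    "airPLS+SG+SNV",
    "airPLS+SNV",
    "SG+MSC",
    "airPLS+SG",
    "SNV",
    "SG+SNV",
    "SG+SNV+MSC",
)

MODELS = ("PLSR", "SVM", "SSA-BP")


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    design: StudyDesign = field(default_factory=default_design)
    profiles: dict[str, MatrixProfile] | None = None
    chains: tuple[str, ...] = CHAIN_SEARCH_SPACE
    models: tuple[str, ...] = MODELS
    calib_fraction: float = 0.7
    n_test_target: int = 30
    # representation feeding SPXY: scatter-normalized so joint distances are
    # not dominated by high-concentration replicate variability
    spxy_chain: str = "airPLS+SG+SNV"
    # CARS
    cars_iterations: int = 50
    cars_folds: int = 5
    cars_max_lv: int = 10
    cars_ensemble_runs: int = 8
    cars_min_votes: int = 3
    # model hyperparameter search
    cv_folds: int = 5
    max_lv: int = 10
    svr_exponents: tuple[int, ...] = tuple(range(-8, 9, 2))
    ssa_pop: int = 30
    ssa_iterations: int = 100
    bp_epochs: int = 2000
    bp_learning_rate: float = 0.05
    hidden_size: int | None = None
    # reduced budget used only to rank preprocessing chains
    search_ssa_iterations: int = 5
    search_ssa_pop: int = 10
    search_bp_epochs: int = 500
    # augmentation study
    secondary_screening: bool = True
    augmentation_chain: str | None = "airPLS+SG"
    augmentation_steps: tuple[int, ...] | None = None

    def svr_grid(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.svr_exponents, dtype=float)


# ---------------------------------------------------------------------------
# preprocessing with per-spectrum caching
# ---------------------------------------------------------------------------


class _SpectraCache:
    """Memoizes per-spectrum transform prefixes (airPLS/SG/SNV) per matrix."""

    def __init__(self, X: np.ndarray):
        self._store: dict[tuple[str, ...], np.ndarray] = {(): np.asarray(X, dtype=float)}

    def get(self, steps: tuple[str, ...]) -> np.ndarray:
        if steps in self._store:
            return self._store[steps]
        prev = self.get(steps[:-1])
        out, _ = apply_chain(prev, "+".join(steps[-1:]))
        self._store[steps] = out
        return out


def _preprocess_pair(chain: str, cal_cache: _SpectraCache, test_caches: list[_SpectraCache]):
    """Fit a chain on the calibration spectra, apply to each test matrix.

    All chains in the search space keep MSC (the only set-level transform) as
    the final step; the per-spectrum prefix is cached per dataset.
    """
    spec = parse_chain(chain)
    steps = spec.steps
    has_msc = "MSC" in steps
    if has_msc and steps[-1] != "MSC":
        raise ValueError("MSC must be the final chain step")
    prefix = steps[:-1] if has_msc else steps
    Z_cal = cal_cache.get(prefix)
    Z_tests = [c.get(prefix) for c in test_caches]
    if has_msc:
        Z_cal, ref = msc(Z_cal)
        Z_tests = [msc(Z, reference=ref)[0] for Z in Z_tests]
    return Z_cal, Z_tests


# ---------------------------------------------------------------------------
# model fitting / ranking helpers
# ---------------------------------------------------------------------------


def _cv_rmse(model: str, X, y, config: ExperimentConfig, seed: int, light: bool) -> float:
    """k-fold CV RMSE used to rank preprocessing chains per model."""
    from sklearn.model_selection import KFold

    if model == "PLSR":
        rmse, _ = pls_rmsecv(X, y, config.max_lv, folds=config.cv_folds, seed=seed)
        return float(rmse.min())
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    sse = 0.0
    for k, (train, test) in enumerate(kf.split(X)):
        pred = _fit_predict(model, X[train], y[train], X[test], config, seed + k, light)
        sse += float(((pred - y[test]) ** 2).sum())
    return float(np.sqrt(sse / len(y)))


def _fit_predict(model, X_train, y_train, X_test, config, seed, light):
    fitted = _fit_model(model, X_train, y_train, config, seed, light)
    return fitted.predict(X_test)


def _fit_model(model: str, X, y, config: ExperimentConfig, seed: int, light: bool = False):
    if model == "PLSR":
        lv = choose_lv_by_cv(X, y, config.max_lv, folds=config.cv_folds, seed=seed)
        return plsr_fit(X, y, lv)
    if model == "SVM":
        grid = config.svr_grid()
        c, g = svr_grid_cv(X, y, grid, grid, folds=config.cv_folds, seed=seed)
        return svr_fit(X, y, c=c, g=g)
    if model == "SSA-BP":
        if light:
            ssa = SSAConfig(pop_size=config.search_ssa_pop,
                            n_iterations=config.search_ssa_iterations, seed=seed)
            epochs = config.search_bp_epochs
        else:
            ssa = SSAConfig(pop_size=config.ssa_pop,
                            n_iterations=config.ssa_iterations, seed=seed)
            epochs = config.bp_epochs
        net, _ = ssa_bp_fit(
            X, y,
            hidden=config.hidden_size,
            ssa_config=ssa,
            bp_epochs=epochs,
            learning_rate=config.bp_learning_rate,
            seed=seed,
        )
        return net
    raise ValueError(f"unknown model {model!r}")


def _best_chain(model, config, cal_cache, y_cal, selected, seed) -> str:
    scores = []
    for chain in config.chains:
        Z_cal, _ = _preprocess_pair(chain, cal_cache, [])
        score = _cv_rmse(model, Z_cal[:, selected], y_cal, config, seed, light=True)
        scores.append((score, chain))
    return min(scores, key=lambda t: t[0])[1]


def _evaluate(model_name, chain, fitted, Z_cal, y_cal, Z_test, y_test, selected):
    pred_cal = fitted.predict(Z_cal[:, selected])
    pred_test = fitted.predict(Z_test[:, selected])
    return metrics.EvalReport(
        model=model_name,
        preprocessing=chain,
        r2_c=metrics.r_squared(y_cal, pred_cal),
        rmsec=metrics.rmsec(y_cal, pred_cal),
        r2_p=metrics.r_squared(y_test, pred_test),
        rmsep=metrics.rmsep(y_test, pred_test),
        n_cal=len(y_cal),
        n_test=len(y_test),
    )


# ---------------------------------------------------------------------------
# shared base pipeline
# ---------------------------------------------------------------------------


def _base_pipeline(config: ExperimentConfig) -> dict:
    """Simulate the study, run CARS on the source matrix, split 7:3 by SPXY."""
    dataset = simulate_study(config.design, seed=config.seed, profiles=config.profiles)
    doff = dataset.for_matrix("dendrobium")
    y_doff = doff.concentrations
    # base wavelength screening on all source-matrix samples; repeated CARS
    # with voting gives the stable characteristic-wavelength list
    Z_screen, _ = apply_chain(doff.intensities, "airPLS+SG")
    cars = ensemble_cars(
        Z_screen,
        y_doff,
        n_runs=config.cars_ensemble_runs,
        min_votes=config.cars_min_votes,
        n_iterations=config.cars_iterations,
        folds=config.cars_folds,
        max_lv=config.cars_max_lv,
        seed=config.seed,
        wavenumbers=doff.grid.wavenumbers,
    )
    Z_split, _ = apply_chain(doff.intensities, config.spxy_chain)
    split = spxy_split(Z_split, y_doff, calib_fraction=config.calib_fraction)
    cal_ids = [doff.sample_ids[i] for i in split.calibration_ids]
    test_ids = [doff.sample_ids[i] for i in split.test_ids]
    return {
        "dataset": dataset,
        "doff": doff,
        "cars": cars,
        "cal": doff.subset(cal_ids),
        "test": doff.subset(test_ids),
    }


def _target_split(dataset: SpectralDataset, name: str, config: ExperimentConfig):
    pool = dataset.for_matrix(name)
    res = random_test_select(
        pool.concentrations,
        n_test=config.n_test_target,
        seed=config.seed,
        sample_ids=pool.sample_ids,
    )
    return pool.subset(res.calibration_ids), pool.subset(res.test_ids)


# ---------------------------------------------------------------------------
# the three studies
# ---------------------------------------------------------------------------


def exp_within_matrix(config: ExperimentConfig) -> tuple[list[metrics.EvalReport], dict]:
    """Within-matrix calibration on the D. officinale-like samples."""
    base = _base_pipeline(config)
    cal, test = base["cal"], base["test"]
    selected = base["cars"].selected_indices
    y_cal, y_test = cal.concentrations, test.concentrations
    cal_cache = _SpectraCache(cal.intensities)
    test_cache = _SpectraCache(test.intensities)
    reports = []
    for m, model in enumerate(config.models):
        seed = config.seed + 1000 * m
        chain = _best_chain(model, config, cal_cache, y_cal, selected, seed)
        Z_cal, (Z_test,) = _preprocess_pair(chain, cal_cache, [test_cache])
        fitted = _fit_model(model, Z_cal[:, selected], y_cal, config, seed)
        reports.append(_evaluate(model, chain, fitted, Z_cal, y_cal, Z_test, y_test, selected))
    return reports, base


def exp_cross_matrix(config: ExperimentConfig) -> tuple[list[metrics.EvalReport], dict]:
    """D. officinale-calibrated models predict the Saffron-like and
    Curcuma-like fixed test sets with the base wavelength selection."""
    base = _base_pipeline(config)
    cal = base["cal"]
    selected = base["cars"].selected_indices
    y_cal = cal.concentrations
    cal_cache = _SpectraCache(cal.intensities)
    targets = {}
    for name in ("saffron", "curcuma"):
        _, test = _target_split(base["dataset"], name, config)
        targets[name] = (test, _SpectraCache(test.intensities))
    reports = []
    for m, model in enumerate(config.models):
        seed = config.seed + 1000 * m
        chain = _best_chain(model, config, cal_cache, y_cal, selected, seed)
        caches = [targets[name][1] for name in targets]
        Z_cal, Z_tests = _preprocess_pair(chain, cal_cache, caches)
        fitted = _fit_model(model, Z_cal[:, selected], y_cal, config, seed)
        for (name, (test, _)), Z_test in zip(targets.items(), Z_tests):
            rep = _evaluate(model, chain, fitted, Z_cal, y_cal, Z_test,
                            test.concentrations, selected)
            rep.model = f"{model}->{name}"
            reports.append(rep)
    base["targets"] = {name: t for name, (t, _) in targets.items()}
    return reports, base


#: After augmentation the per-target best models of the source study.
TARGET_MODEL = {"saffron": "SVM", "curcuma": "PLSR"}


def exp_augmentation(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Incremental augmentation with optional secondary wavelength screening.

    The Saffron-like and Curcuma-like test sets stay fixed across steps; the
    training set grows by five samples of each target matrix per step (low to
    high concentration), and CARS is optionally re-run on each augmented
    training set.  SVM predicts the Saffron-like target and PLSR the
    Curcuma-like target.
    """
    base = _base_pipeline(config)
    dataset = base["dataset"]
    cal = base["cal"]
    base_selected = base["cars"].selected_indices

    pools, tests = {}, {}
    for name in ("saffron", "curcuma"):
        pool, test = _target_split(dataset, name, config)
        order = np.argsort(pool.concentrations, kind="stable")
        pools[name] = [pool.sample_ids[i] for i in order]
        tests[name] = test

    schedule = augmentation_schedule(pools["saffron"], pools["curcuma"], cal.sample_ids)
    if config.augmentation_steps is not None:
        wanted = set(config.augmentation_steps)
        schedule = [s for s in schedule if s.step_index in wanted]

    chain = config.augmentation_chain or "airPLS+SG"
    test_caches = {name: _SpectraCache(tests[name].intensities) for name in tests}

    rows = []
    wavelengths: dict[int, np.ndarray] = {}
    for step in schedule:
        train = dataset.subset(step.training_ids)
        y_train = train.concentrations
        train_cache = _SpectraCache(train.intensities)
        Z_train, Z_tests = _preprocess_pair(
            chain, train_cache, [test_caches[n] for n in tests]
        )
        if config.secondary_screening:
            sel = ensemble_cars(
                Z_train,
                y_train,
                n_runs=config.cars_ensemble_runs,
                min_votes=config.cars_min_votes,
                seed=config.seed + 100 * step.step_index,
                n_iterations=config.cars_iterations,
                folds=config.cars_folds,
                max_lv=config.cars_max_lv,
                wavenumbers=train.grid.wavenumbers,
            )
            selected = sel.selected_indices
            wavelengths[step.step_index] = sel.selected_wavenumbers
        else:
            selected = base_selected
        row = {
            "step": step.step_index,
            "n_train": len(step.training_ids),
            "added_saffron": step.added_saffron,
            "added_curcuma": step.added_curcuma,
            "n_wavelengths": len(selected),
        }
        for (name, test), Z_test in zip(tests.items(), Z_tests):
            model = TARGET_MODEL[name]
            fitted = _fit_model(model, Z_train[:, selected], y_train, config,
                                config.seed + step.step_index)
            pred = fitted.predict(Z_test[:, selected])
            row[f"R2_p_{name}"] = metrics.r_squared(test.concentrations, pred)
            row[f"RMSEP_{name}"] = metrics.rmsep(test.concentrations, pred)
        rows.append(row)
    table = pd.DataFrame(rows)
    base["wavelengths"] = wavelengths
    base["tests"] = tests
    return table, base
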