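"""Linear population readout of Go vs Nogo from 1-ms-binned pseudo-populations.

Units recorded in separate sessions are combined into pseudo-trials by
randomly pairing trial indices within each stimulus class. Each unit's
binned counts are z-scored against its own pooled mean/SD and rectified
(absolute z-scores); per-trial feature vectors are the across-unit
average of these normalized counts (length = number of bins). A linear
maximum-margin classifier (cost 1) is trained on a random 80% of trials
and scored on the held-out 20%; hit/false-alarm proportions convert to d'
with the same 0.05/0.95 clamp as the behavioral analysis. Resampling
variants sweep unit count and monotonic subclass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psychometrics import compute_dprime
from .stimuli import is_unmodulated
from .unit_metrics import best_window_dprime, neurometric_threshold, monotonicity_index

__all__ = [
    "DecoderConfig",
    "DecoderResult",
    "PopulationTensor",
    "bin_unit_counts",
    "build_population_tensor",
    "decode",
    "unit_count_curve",
    "mi_subpopulation_decode",
    "population_cv",
]


@dataclass
class DecoderConfig:
    n_iterations: int = 250
    train_fraction: float = 0.8
    cost: float = 1.0
    seed: int = 0
    normalization: str = "pooled"  # pooled | per-bin z-scoring
    repair_each_iteration: bool = True


@dataclass
class DecoderResult:
    go_depth_db: float
    mean_dprime: float
    sd_dprime: float
    n_iterations: int
    n_units: int
    bin_width_ms: float
    cost: float
    seed: int
    per_iteration_dprime: np.ndarray = field(repr=False, default=None)


def bin_unit_counts(spikes, window: tuple[float, float], bin_width_ms: float) -> np.ndarray:
    """(trials x bins) spike counts with half-open bins [t, t + width).

    A spike exactly on an edge lands in the later bin.
    """
    t0, t1 = window
    width = bin_width_ms / 1000.0
    n_bins = int(round((t1 - t0) / width))
    edges = t0 + np.arange(n_bins + 1) * width
    out = np.zeros((len(spikes), n_bins), dtype=float)
    for i, s in enumerate(spikes):
        s = np.asarray(s, float)
        s = s[(s >= t0) & (s < edges[-1])]
        if s.size:
            idx = np.floor((s - t0) / width).astype(int)
            np.add.at(out[i], idx, 1.0)
    return out


class PopulationTensor:
    """Per-unit binned counts grouped by stimulus class, plus one realized
    pseudo-trial pairing.

    Attributes
    ----------
    counts : (N, T, N_bin) raw-count array for the realized pairing.
    normalized : same shape, absolute z-scores (per-unit pooled mean/SD).
    labels : length-T array of class labels ("go"/"nogo" style strings).
    """

    def __init__(self, unit_class_counts, unit_ids, classes, bin_width_ms,
                 window, seed=0, normalization="pooled"):
        self.unit_class_counts = unit_class_counts  # list over units: {class: (n_u, bins)}
        self.unit_ids = list(unit_ids)
        self.classes = list(classes)
        self.bin_width_ms = float(bin_width_ms)
        self.window = tuple(window)
        self.seed = seed
        self.normalization = normalization
        self._norm_params = []
        self.dropped_units = []
        for i, by_class in enumerate(unit_class_counts):
            pooled = np.vstack([by_class[c] for c in self.classes])
            if normalization == "per-bin":
                mu = pooled.mean(axis=0)
                sd = pooled.std(axis=0)
                sd[sd == 0] = 1.0
            else:
                mu = float(pooled.mean())
                sd = float(pooled.std())
                if sd == 0.0:
                    self.dropped_units.append(self.unit_ids[i])
                    sd = 1.0
            self._norm_params.append((mu, sd))
        # balanced trial count per class across units
        self.trials_per_class = min(
            min(by_class[c].shape[0] for c in self.classes)
            for by_class in unit_class_counts
        )
        rng = np.random.default_rng(seed)
        self.counts, self.normalized, self.labels = self.sample_pseudotrials(rng)

    @property
    def n_units(self):
        return len(self.unit_class_counts)

    @property
    def n_bins(self):
        return self.unit_class_counts[0][self.classes[0]].shape[1]

    def sample_pseudotrials(self, rng, unit_subset=None):
        """Randomly pair trial indices across units within each class."""
        units = range(self.n_units) if unit_subset is None else unit_subset
        units = list(units)
        t = self.trials_per_class
        counts = np.zeros((len(units), t * len(self.classes), self.n_bins))
        labels = np.concatenate([[c] * t for c in self.classes])
        for row, i in enumerate(units):
            col = 0
            for c in self.classes:
                arr = self.unit_class_counts[i][c]
                pick = rng.choice(arr.shape[0], size=t, replace=False)
                counts[row, col:col + t] = arr[pick]
                col += t
        norm = np.empty_like(counts)
        for row, i in enumerate(units):
            mu, sd = self._norm_params[i]
            norm[row] = np.abs((counts[row] - mu) / sd)
        return counts, norm, labels


def build_population_tensor(
    units,
    go_depths,
    window: tuple[float, float] = (0.0, 0.4),
    bin_width_ms: float = 1.0,
    seed: int = 0,
    require_threshold: bool = True,
    normalization: str = "pooled",
) -> PopulationTensor:
    """Assemble a pseudo-population tensor for Go depths vs Nogo.

    Only units with a defined FR-based neurometric threshold are included
    when ``require_threshold`` is set. Classes are balanced by subsampling
    to the smallest per-class trial count.
    """
    go_depths = [float(d) for d in np.atleast_1d(go_depths)]
    classes = [f"go:{d:g}" for d in go_depths] + ["nogo"]
    kept_units, unit_class_counts = [], []
    for u in units:
        if require_threshold:
            nm = best_window_dprime(u)
            thr, flag = neurometric_threshold(nm["depths_db"], nm["dprime"])
            if thr is None:
                continue
        is_go = (u.trials["type"] == "go").to_numpy()
        depths = u.trials["depth_db"].to_numpy(float)
        by_class = {}
        ok = True
        for d in go_depths:
            idx = np.where(is_go & (depths == d))[0]
            if idx.size == 0:
                ok = False
                break
            by_class[f"go:{d:g}"] = bin_unit_counts(
                [u.spikes[i] for i in idx], window, bin_width_ms
            )
        idx = np.where(~is_go)[0]
        if not ok or idx.size == 0:
            raise ValueError(f"unit {u.unit_id} lacks a requested condition")
        by_class["nogo"] = bin_unit_counts(
            [u.spikes[i] for i in idx], window, bin_width_ms
        )
        kept_units.append(u.unit_id)
        unit_class_counts.append(by_class)
    if not kept_units:
        raise ValueError("no units qualify for the population tensor")
    return PopulationTensor(
        unit_class_counts, kept_units, classes, bin_width_ms, window,
        seed=seed, normalization=normalization,
    )


def _svm_dprime(x_go, x_nogo, cfg, rng):
    """One 80/20 split -> (hit rate, FA rate) of a linear SVM readout."""
    from sklearn.svm import SVC

    n_go, n_nogo = x_go.shape[0], x_nogo.shape[0]
    for _attempt in range(10):
        g_perm = rng.permutation(n_go)
        n_perm = rng.permutation(n_nogo)
        g_tr = g_perm[: max(1, int(round(cfg.train_fraction * n_go)))]
        g_te = g_perm[g_tr.size:]
        n_tr = n_perm[: max(1, int(round(cfg.train_fraction * n_nogo)))]
        n_te = n_perm[n_tr.size:]
        if g_te.size and n_te.size:
            break
    else:  # pragma: no cover - degenerate split loop
        raise RuntimeError("could not draw a non-degenerate train/test split")
    x_train = np.vstack([x_go[g_tr], x_nogo[n_tr]])
    y_train = np.concatenate([np.ones(g_tr.size), np.zeros(n_tr.size)])
    clf = SVC(kernel="linear", C=cfg.cost)
    clf.fit(x_train, y_train)
    hit = float(np.mean(clf.predict(x_go[g_te]) == 1.0))
    fa = float(np.mean(clf.predict(x_nogo[n_te]) == 1.0))
    return hit, fa


def decode(tensor: PopulationTensor, go_depth_db: float,
           config: DecoderConfig | None = None,
           unit_subset=None) -> DecoderResult:
    """Linear readout of one Go depth vs Nogo, mean +/- SD d' over iterations.

    Each iteration re-pairs pseudo-trials across units (no cross-unit
    noise correlation is asserted), averages normalized binned counts
    across units into per-trial feature vectors, fits the linear SVM on a
    random 80% and scores the held-out 20%.
    """
    cfg = config or DecoderConfig()
    rng = np.random.default_rng(cfg.seed)
    go_label = f"go:{float(go_depth_db):g}"
    if go_label not in tensor.classes:
        raise KeyError(f"{go_label} not among tensor classes {tensor.classes}")
    if tensor.trials_per_class < 5:
        raise ValueError("too few trials per class to split 80/20")
    dps = np.empty(cfg.n_iterations)
    n_units = tensor.n_units if unit_subset is None else len(unit_subset)
    for it in range(cfg.n_iterations):
        if cfg.repair_each_iteration or it == 0:
            _, norm, labels = tensor.sample_pseudotrials(rng, unit_subset)
            feats = norm.mean(axis=0)  # (trials, bins) across-unit average
            x_go = feats[labels == go_label]
            x_nogo = feats[labels == "nogo"]
        hit, fa = _svm_dprime(x_go, x_nogo, cfg, rng)
        dps[it] = compute_dprime(hit, fa)
    return DecoderResult(
        go_depth_db=float(go_depth_db), mean_dprime=float(dps.mean()),
        sd_dprime=float(dps.std(ddof=0)), n_iterations=cfg.n_iterations,
        n_units=n_units, bin_width_ms=tensor.bin_width_ms, cost=cfg.cost,
        seed=cfg.seed, per_iteration_dprime=dps,
    )


def unit_count_curve(tensor: PopulationTensor, go_depth_db: float,
                     fractions=None, config: DecoderConfig | None = None):
    """Mean +/- SD decoder d' vs subsampled unit count (10-100% of units)."""
    cfg = config or DecoderConfig()
    if fractions is None:
        fractions = np.arange(0.1, 1.01, 0.1)
    if tensor.n_units < 10:
        raise ValueError("unit-count curve needs >=10 units")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for frac in fractions:
        n = int(round(frac * tensor.n_units))
        if n < 1:
            raise ValueError(f"fraction {frac} yields no units")
        dps = np.empty(cfg.n_iterations)
        for it in range(cfg.n_iterations):
            subset = rng.choice(tensor.n_units, size=n, replace=False)
            _, norm, labels = tensor.sample_pseudotrials(rng, subset)
            feats = norm.mean(axis=0)
            go_label = f"go:{float(go_depth_db):g}"
            hit, fa = _svm_dprime(
                feats[labels == go_label], feats[labels == "nogo"], cfg, rng
            )
            dps[it] = compute_dprime(hit, fa)
        rows.append({
            "fraction": float(frac), "n_units": n,
            "mean_dprime": float(dps.mean()), "sd_dprime": float(dps.std(ddof=0)),
        })
    return rows


def mi_subpopulation_decode(units, monotonic_class: str, go_depth_db: float,
                            n: int = 10, window=(0.0, 0.4), bin_width_ms=1.0,
                            config: DecoderConfig | None = None) -> DecoderResult:
    """Decode with random n-unit draws from one monotonic class.

    Units are classified increasing/decreasing by their monotonicity
    index; each iteration draws ``n`` units of the class without
    replacement and runs the standard readout.
    """
    cfg = config or DecoderConfig()
    chosen = []
    for u in units:
        nm = best_window_dprime(u)
        if 0.0 not in nm["depths_db"]:
            continue
        _, klass = monotonicity_index(nm["depths_db"], nm["fr_mean"])
        if klass == monotonic_class:
            chosen.append(u)
    if len(chosen) < n:
        raise ValueError(
            f"monotonic class {monotonic_class!r} has {len(chosen)} units, need {n}"
        )
    tensor = build_population_tensor(
        chosen, [go_depth_db], window=window, bin_width_ms=bin_width_ms,
        seed=cfg.seed, require_threshold=False,
    )
    rng = np.random.default_rng(cfg.seed)
    dps = np.empty(cfg.n_iterations)
    go_label = f"go:{float(go_depth_db):g}"
    for it in range(cfg.n_iterations):
        subset = rng.choice(tensor.n_units, size=n, replace=False)
        _, norm, labels = tensor.sample_pseudotrials(rng, subset)
        feats = norm.mean(axis=0)
        hit, fa = _svm_dprime(
            feats[labels == go_label], feats[labels == "nogo"], cfg, rng
        )
        dps[it] = compute_dprime(hit, fa)
    return DecoderResult(
        go_depth_db=float(go_depth_db), mean_dprime=float(dps.mean()),
        sd_dprime=float(dps.std(ddof=0)), n_iterations=cfg.n_iterations,
        n_units=n, bin_width_ms=bin_width_ms, cost=cfg.cost, seed=cfg.seed,
        per_iteration_dprime=dps,
    )


def population_cv(tensor: PopulationTensor) -> dict:
    """Across-bin CV of the population-summed count, per pseudo-trial.

    For each trial the unit-summed count is computed per bin; CV is the SD
    across bins divided by the mean across bins. Zero-mean trials are
    flagged and skipped.
    """
    summed = tensor.counts.sum(axis=0)  # (trials, bins)
    means = summed.mean(axis=1)
    ok = means > 0
    cvs = np.full(means.shape, np.nan)
    cvs[ok] = summed[ok].std(axis=1, ddof=0) / means[ok]
    out = {"per_trial_cv": cvs, "n_skipped": int(np.sum(~ok)), "by_class": {}}
    for c in tensor.classes:
        mask = (tensor.labels == c) & ok
        out["by_class"][c] = {
            "median_cv": float(np.median(cvs[mask])) if mask.any() else np.nan,
            "n": int(mask.sum()),
        }
    return out
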