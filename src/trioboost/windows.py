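"""SNP-window imputation: per-locus boosting models trained on parents.

For each un-typed locus, a window of the nearest ``L/2`` typed loci on each
side (same chromosome; deficits near a chromosome end are compensated on the
long side, up to ``L`` features total) provides the classifier features.
Training rows are the *parents'* phased haplotypes at the window loci, the
label being the parent's allele at the target locus; offspring rows are never
used for training.  Each masked offspring entry is then predicted by weighted
majority voting of the fitted ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import boosting
from .simulate import TrioDataset, VERSION_FRACTIONS

__all__ = [
    "SnpWindow",
    "ImputationTask",
    "build_window",
    "select_window_size",
    "impute_snp",
    "impute_dataset",
    "EmptyWindowError",
    "DEFAULT_WINDOW_BY_DENSITY",
]

log = logging.getLogger(__name__)

#: Window sizes selected by validation scanning at each panel density.
DEFAULT_WINDOW_BY_DENSITY = {"1k": 22, "5k": 10, "10k": 10}

_FITTERS = {
    "AB": boosting.fit_adaboost,
    "LB": boosting.fit_logitboost,
    "TB": boosting.fit_totalboost,
}


class EmptyWindowError(ValueError):
    """No typed loci available on the target's chromosome."""


@dataclass(frozen=True)
class SnpWindow:
    """Feature loci flanking one un-typed target locus."""

    target: int
    features: np.ndarray  # global locus indices, left block then right block
    chrom: int
    size: int  # nominal L

    def __post_init__(self):
        if self.target in self.features:
            raise ValueError("window features must exclude the target")


@dataclass(frozen=True)
class ImputationTask:
    """One imputation run configuration."""

    method: str  # "AB" | "LB" | "TB"
    window_size: int = 10
    n_trees: int = 100
    level: str = "allele"  # "allele" | "genotype"
    nu: float = 0.05
    depth: int = 1

    def __post_init__(self):
        if self.window_size < 2 or self.window_size % 2:
            raise ValueError("window size L must be an even integer >= 2")
        if self.n_trees < 1:
            raise ValueError("tree count M must be >= 1")
        if self.method not in _FITTERS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.level not in ("allele", "genotype"):
            raise ValueError(f"unknown level {self.level!r}")


def build_window(
    target: int,
    typed_loci: np.ndarray,
    L: int,
    chrom_bounds: tuple,
    chrom: int = 0,
) -> SnpWindow:
    """Nearest ``L/2`` typed loci each side of ``target`` (by locus index).

    ``typed_loci`` are sorted global indices; only those inside
    ``chrom_bounds = (lo, hi)`` are eligible.  Near a chromosome end the
    deficit on the short side is compensated on the long side, truncated at
    the boundary, so up to ``L`` features total are returned.
    """
    lo, hi = chrom_bounds
    if not (lo <= target < hi):
        raise ValueError("target outside chromosome bounds")
    typed = np.asarray(typed_loci)
    typed = typed[(typed >= lo) & (typed < hi) & (typed != target)]
    if len(typed) == 0:
        raise EmptyWindowError(f"no typed loci on chromosome of locus {target}")
    pos = int(np.searchsorted(typed, target))
    half = L // 2
    n_left, n_right = pos, len(typed) - pos
    want_left = half + max(0, half - n_right)
    want_right = half + max(0, half - n_left)
    take_left = min(n_left, want_left)
    take_right = min(n_right, want_right)
    feats = np.concatenate([typed[pos - take_left : pos], typed[pos : pos + take_right]])
    return SnpWindow(target, feats, chrom, L)


def _fill_unknown_features(F: np.ndarray, train_major: np.ndarray) -> np.ndarray:
    """Replace NaN features by the training-set per-feature major value."""
    F = F.copy()
    nan = np.isnan(F)
    if nan.any():
        F[nan] = np.broadcast_to(train_major, F.shape)[nan]
    return F


def _train_predict(Xtr, ytr, Xte, task: ImputationTask):
    """Fit one boosting model on parents and predict {0,1} for ``Xte`` rows."""
    classes = np.unique(ytr)
    if len(classes) < 2 or len(ytr) < 2:
        # monomorphic target in parents: constant prediction, no model fit
        value = float(classes[0]) if len(classes) else 0.0
        return np.full(Xte.shape[0], value), None
    y_signed = np.where(ytr == 1, 1.0, -1.0)
    fitter = _FITTERS[task.method]
    if task.method == "TB":
        model = fitter(Xtr, y_signed, M=task.n_trees, nu=task.nu, depth=task.depth)
    else:
        model = fitter(Xtr, y_signed, M=task.n_trees, depth=task.depth)
    labels, _ = boosting.predict_ensemble(model, Xte)
    return np.where(labels > 0, 1.0, 0.0), model


def impute_snp(
    dataset: TrioDataset,
    target: int,
    window: SnpWindow,
    method: str = "LB",
    M: int = 100,
    task: Optional[ImputationTask] = None,
) -> np.ndarray:
    """Predict the masked offspring haplotype values at one target locus.

    Training rows are parent haplotypes with a known value at ``target``
    (rows with an unknown target are excluded from training but are imputed
    the same way as any other).  Returns the predicted allele (0/1) for each
    offspring haplotype row that is unknown at the target, in row order.
    """
    if task is None:
        task = ImputationTask(method=method, window_size=len(window.features) + len(window.features) % 2 or 2, n_trees=M)
    H = dataset.haplos
    n_trios = dataset.n_trios
    par = H[: 2 * n_trios].reshape(4 * n_trios, -1)
    off = H[2 * n_trios :].reshape(2 * n_trios, -1)
    known = ~np.isnan(par[:, target])
    Xtr_raw = par[known][:, window.features]
    ytr = par[known, target]
    train_major = _major_values(Xtr_raw)
    Xtr = _fill_unknown_features(Xtr_raw, train_major)
    unknown_rows = np.isnan(off[:, target])
    if known.sum() < 2:
        log.warning("locus %d: empty training set, falling back to major value", target)
        return np.zeros(int(unknown_rows.sum()))
    Xte = _fill_unknown_features(off[unknown_rows][:, window.features], train_major)
    pred, _ = _train_predict(Xtr, ytr, Xte, task)
    return pred


def _major_values(X: np.ndarray) -> np.ndarray:
    """Per-feature majority value among non-NaN entries (ties -> 0)."""
    with np.errstate(invalid="ignore"):
        m = np.nanmean(X, axis=0)
    m = np.where(np.isnan(m), 0.0, m)
    return (m > 0.5).astype(float)


def impute_dataset(
    dataset: TrioDataset,
    method: str = "LB",
    L: Optional[int] = None,
    M: int = 100,
    nu: float = 0.05,
    level: str = "allele",
    depth: int = 1,
) -> TrioDataset:
    """Fill every unknown offspring entry of a masked dataset.

    One model is trained per target locus (windows are built over loci typed
    in the offspring panel when the mask is shared, otherwise over all loci,
    with offspring feature unknowns filled by the parent-training major
    value).  Parents are left untouched.  Returns a completed copy.
    """
    if L is None:
        L = DEFAULT_WINDOW_BY_DENSITY.get(dataset.density or "", 10)
    task = ImputationTask(method=method, window_size=L, n_trees=M, level=level, nu=nu, depth=depth)
    out = dataset.copy()
    H = out.haplos
    n_trios = out.n_trios
    n_loci = out.n_loci
    off0 = 2 * n_trios
    off_h = H[off0:].reshape(2 * n_trios, n_loci)  # view: two rows per offspring

    unknown_any = np.isnan(off_h).any(axis=0)
    targets = np.flatnonzero(unknown_any)
    if len(targets) == 0:
        return out

    # typed loci for window construction: panel loci under a shared mask,
    # otherwise every locus (parents are typed everywhere)
    if out.mask is not None and out.mask.mode == "shared_panel":
        typed = np.flatnonzero(~out.mask.masked.any(axis=0))
    else:
        typed = np.flatnonzero(~np.isnan(off_h).all(axis=0)) if out.mask is None else np.arange(n_loci)

    offsets = out.gmap.chrom_offsets
    chrom_of = out.gmap.chrom_of_locus()
    par = H[:off0].reshape(4 * n_trios, n_loci)

    if level == "genotype":
        _impute_genotype_level(out, targets, typed, offsets, chrom_of, task)
        return out

    for t in targets:
        c = chrom_of[t]
        window = build_window(int(t), typed, L, (offsets[c], offsets[c + 1]), int(c))
        known = ~np.isnan(par[:, t])
        ytr = par[known, t]
        Xtr_raw = par[known][:, window.features]
        train_major = _major_values(Xtr_raw)
        Xtr = _fill_unknown_features(Xtr_raw, train_major)
        rows = np.isnan(off_h[:, t])
        if known.sum() < 2:
            log.warning("locus %d: empty training set, using major value", t)
            off_h[rows, t] = 0.0
            continue
        Xte = _fill_unknown_features(off_h[rows][:, window.features], train_major)
        pred, _ = _train_predict(Xtr, ytr, Xte, task)
        off_h[rows, t] = pred
    return out


def _impute_genotype_level(out, targets, typed, offsets, chrom_of, task):
    """Dosage-feature mode for unphased data.

    Features are parent genotype dosages (0/1/2); two binary classifiers per
    locus predict minor-allele carriage (g >= 1) and minor homozygosity
    (g == 2), which combine to a dosage in {0, 1, 2}.  Filled offspring
    entries get an arbitrary phase split (dosage 1 -> 0|1).
    """
    n_trios = out.n_trios
    G = out.genotypes("coded")
    par_g = G[: 2 * n_trios]
    off_g = G[2 * n_trios :]
    L = task.window_size
    for t in targets:
        c = chrom_of[t]
        window = build_window(int(t), typed, L, (offsets[c], offsets[c + 1]), int(c))
        known = ~np.isnan(par_g[:, t])
        rows = np.flatnonzero(np.isnan(off_g[:, t]))
        if known.sum() < 2:
            off_g[rows, t] = 0.0
        else:
            Xtr_raw = par_g[known][:, window.features]
            major = _major_values(Xtr_raw)
            Xtr = _fill_unknown_features(Xtr_raw, major)
            Xte = _fill_unknown_features(off_g[rows][:, window.features], major)
            g = par_g[known, t]
            carry, _ = _train_predict(Xtr, (g >= 1).astype(float), Xte, task)
            homo, _ = _train_predict(Xtr, (g == 2).astype(float), Xte, task)
            dosage = np.where(carry > 0, np.where(homo > 0, 2.0, 1.0), 0.0)
            off_g[rows, t] = dosage
        for r in rows:
            d = off_g[r, t]
            out.haplos[2 * n_trios + r, 0, t] = 1.0 if d == 2 else 0.0
            out.haplos[2 * n_trios + r, 1, t] = 1.0 if d >= 1 else 0.0


def select_window_size(
    dataset: TrioDataset,
    candidates: Optional[Sequence[int]] = None,
    method: str = "LB",
    seed=0,
    M: int = 100,
    validation_fraction: float = 0.05,
) -> int:
    """Window size with the best held-out imputation accuracy.

    With no candidates the density default is returned (10 for the 5k/10k
    panels, 22 for 1k).  Otherwise an extra ``validation_fraction`` of the
    currently known offspring entries is masked, each candidate ``L`` imputes
    them, and the ``L`` with the highest mean validation concordance wins
    (ties to the smaller ``L``).
    """
    if candidates is None:
        return DEFAULT_WINDOW_BY_DENSITY.get(dataset.density or "", 10)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    for L in candidates:
        if L < 2 or L % 2:
            raise ValueError("candidate window sizes must be even integers >= 2")
    if len(candidates) == 1:
        return candidates[0]

    rng = np.random.default_rng(seed)
    n_trios = dataset.n_trios
    off0 = 2 * n_trios
    off = dataset.haplos[off0:]
    known_cols = np.flatnonzero(~np.isnan(off.reshape(2 * n_trios, -1)).any(axis=0))
    n_val = max(1, int(round(validation_fraction * len(known_cols))))
    val_cols = np.sort(rng.choice(known_cols, n_val, replace=False))

    held = dataset.copy()
    truth_vals = dataset.haplos[off0:, :, val_cols].copy()
    held.haplos[off0:, :, val_cols] = np.nan
    if held.mask is not None:
        held.mask.masked[:, val_cols] = True

    best_L, best_acc = None, -np.inf
    for L in sorted(candidates):
        done = impute_dataset(held, method=method, L=L, M=M)
        pred = done.haplos[off0:, :, val_cols]
        acc = float((pred == truth_vals).mean())
        if acc > best_acc + 1e-12:
            best_L, best_acc = L, acc
    return best_L
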