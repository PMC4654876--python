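"""Genomic and pedigree prediction under sire-family cross-validation.

Animals are split into k (default 10) folds by whole sire families so no
half-sib group straddles a training/validation boundary, with every breed
type represented in every fold.  For each fold the validation animals'
records are withheld and breeding values are predicted by GBLUP (genomic
relationship matrix), PBLUP (pedigree numerator relationship matrix) or
BayesC-pi GEBVs (summed SNP effects).  Realized accuracy is the
correlation between predictions and withheld adjusted phenotypes divided
by sqrt(h2), averaged across folds; the regression slope of y* on the
prediction measures bias (1 = unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .bayescpi import BayesCPi, ChainConfig
from .data import GenotypeMatrix, RelationshipMatrix
from .exceptions import ConfigError, DataError

METHODS = ("pblup", "gblup", "bayescpi")


@dataclass
class FoldAssignment:
    """Sire-family-disjoint fold labels (1..k) per animal."""

    fold_id: pd.Series          # indexed by animal_id
    k: int
    sire_of: pd.Series
    breed_of: pd.Series

    def validate(self) -> None:
        per_sire = self.fold_id.groupby(self.sire_of).nunique()
        if (per_sire > 1).any():
            raise DataError("a sire family straddles two folds")
        folds = set(self.fold_id.unique())
        if folds != set(range(1, self.k + 1)):
            raise DataError("fold labels must cover 1..k")
        for f in range(1, self.k + 1):
            breeds_in = set(self.breed_of[self.fold_id == f])
            missing = set(self.breed_of.unique()) - breeds_in
            if missing:
                raise DataError(f"fold {f} lacks breed(s) {sorted(missing)}")

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero((self.fold_id == fold).to_numpy())


def make_folds(pedigree: pd.DataFrame, breeds, k: int = 10,
               seed: int = 0) -> FoldAssignment:
    """Pack whole sire families into k breed-covered, size-balanced folds.

    Families (animals sharing a sire; animals with unknown sires are
    singleton families) are assigned greedily, largest first, to the
    currently smallest fold; a repair pass then swaps families to restore
    any missing breed coverage.  Deterministic given the seed.
    """
    animals = pedigree["animal_id"].to_numpy()
    sires = pedigree["sire_id"].copy()
    unknown = sires.isna()
    sires = sires.astype(object)
    sires[unknown.to_numpy()] = [f"_founder_{a}" for a in animals[unknown.to_numpy()]]
    sire_of = pd.Series(sires.to_numpy(), index=animals, name="sire_id")
    breed_of = pd.Series(np.asarray(breeds), index=animals, name="breed")

    fam_names = pd.unique(sire_of)
    if len(fam_names) < k:
        raise ConfigError(
            f"need at least k={k} sire families, found {len(fam_names)}"
        )
    breed_counts = breed_of.value_counts()
    small = breed_counts[breed_counts < k]
    if len(small):
        raise ConfigError(
            f"breed {small.index[0]!r} has only {small.iloc[0]} animals; "
            f"cannot appear in all {k} folds"
        )

    rng = np.random.default_rng(seed)
    fam_members = {f: list(animals[(sire_of == f).to_numpy()]) for f in fam_names}
    order = sorted(fam_names, key=lambda f: (-len(fam_members[f]), str(f)))
    # shuffle among equal sizes for seed-dependence
    sizes = {}
    for f in order:
        sizes.setdefault(len(fam_members[f]), []).append(f)
    order = []
    for size in sorted(sizes, reverse=True):
        group = sizes[size]
        rng.shuffle(group)
        order.extend(group)

    fold_of_family: dict = {}
    fold_sizes = np.zeros(k, dtype=int)
    for f in order:
        target = int(np.argmin(fold_sizes))
        fold_of_family[f] = target + 1
        fold_sizes[target] += len(fam_members[f])

    fold_id = pd.Series(
        [fold_of_family[s] for s in sire_of], index=animals, name="fold"
    )
    fold_id = _repair_breed_coverage(fold_id, sire_of, breed_of, k, rng)
    fa = FoldAssignment(fold_id=fold_id, k=k, sire_of=sire_of, breed_of=breed_of)
    fa.validate()
    return fa


def _repair_breed_coverage(fold_id, sire_of, breed_of, k, rng,
                           max_pass: int = 20):
    """Swap sire families between folds until every breed is in every fold."""
    for _ in range(max_pass):
        fixed = True
        for f in range(1, k + 1):
            missing = set(breed_of.unique()) - set(breed_of[fold_id == f])
            for breed in sorted(missing):
                fixed = False
                # find a donor family with that breed in a fold that keeps
                # coverage after losing it
                donors = sire_of[(breed_of == breed).to_numpy()].unique()
                moved = False
                for fam in donors:
                    src = fold_id[sire_of == fam].iloc[0]
                    if src == f:
                        continue
                    src_rest = (fold_id == src) & (sire_of != fam).to_numpy()
                    if set(breed_of.unique()) <= set(breed_of[src_rest]):
                        fold_id = fold_id.where((sire_of != fam).to_numpy(), f)
                        moved = True
                        break
                if not moved:
                    raise DataError(
                        f"cannot achieve breed coverage for {breed!r} in fold {f}"
                    )
        if fixed:
            break
    return fold_id


# ---- BLUP prediction ----------------------------------------------------


def _blup_kernel(y_train, K, train_idx, val_idx, sigma2_a, sigma2_e,
                 ridge=1e-6):
    """Kernel-regression route: a_hat_v = K_vt (K_tt + lambda I)^-1 (y - mu),
    with the GLS intercept mu_hat = (1'V^-1 1)^-1 1'V^-1 y."""
    lam = sigma2_e / sigma2_a
    Ktt = K[np.ix_(train_idx, train_idx)] + ridge * np.eye(len(train_idx))
    C = cho_factor(Ktt + lam * np.eye(len(train_idx)))
    ones = np.ones(len(train_idx))
    Vi1 = cho_solve(C, ones)
    mu = float(ones @ cho_solve(C, y_train)) / float(ones @ Vi1)
    alpha = cho_solve(C, y_train - mu)
    return K[np.ix_(val_idx, train_idx)] @ alpha, mu


def _blup_mme(y_train, K, train_idx, val_idx, sigma2_a, sigma2_e,
              ridge=1e-6):
    """Mixed-model-equations route over all animals:

        [ 1'1      1'Z          ] [mu]   [1'y]
        [ Z'1  Z'Z + lambda K^-1] [a ] = [Z'y]

    with Z the training-record incidence matrix."""
    n_all = K.shape[0]
    lam = sigma2_e / sigma2_a
    Kr = K + ridge * np.eye(n_all)
    Kinv = np.linalg.inv(Kr)
    nt = len(train_idx)
    ZtZ = np.zeros((n_all, n_all))
    ZtZ[train_idx, train_idx] = 1.0
    top = np.concatenate([[nt], np.bincount(train_idx, minlength=n_all)])
    Zty = np.zeros(n_all)
    Zty[train_idx] = y_train
    lhs = np.zeros((n_all + 1, n_all + 1))
    lhs[0, 0] = nt
    lhs[0, 1:] = top[1:]
    lhs[1:, 0] = top[1:]
    lhs[1:, 1:] = ZtZ + lam * Kinv
    rhs = np.concatenate([[y_train.sum()], Zty])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:][val_idx], float(sol[0])


def gblup_predict(y_star_train, relationship, train_idx, val_idx,
                  sigma2_a, sigma2_e, route: str = "kernel",
                  ridge: float = 1e-6) -> np.ndarray:
    """Breeding values for validation animals under y* = 1 mu + Z a + e.

    Validation animals carry no records; their EBVs come from the
    relationship matrix ties to the training records.  The two algebraic
    routes ("kernel" and "mme") agree to numerical precision.
    """
    if sigma2_a <= 0 or sigma2_e <= 0:
        raise ConfigError("variance components must be positive")
    K = (relationship.values if isinstance(relationship, RelationshipMatrix)
         else np.asarray(relationship, dtype=float))
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if train_idx.max(initial=-1) >= K.shape[0] or val_idx.max(initial=-1) >= K.shape[0]:
        raise DataError("animal index outside the relationship matrix")
    y_train = np.asarray(y_star_train, dtype=float)
    if len(y_train) != len(train_idx):
        raise DataError("training phenotype length must match train_idx")
    if route == "kernel":
        ebv, _ = _blup_kernel(y_train, K, train_idx, val_idx, sigma2_a,
                              sigma2_e, ridge)
    elif route == "mme":
        ebv, _ = _blup_mme(y_train, K, train_idx, val_idx, sigma2_a,
                           sigma2_e, ridge)
    else:
        raise ConfigError("route must be 'kernel' or 'mme'")
    return ebv


def pblup_predict(y_star_train, a_mat, train_idx, val_idx, sigma2_a,
                  sigma2_e, route: str = "kernel") -> np.ndarray:
    """PBLUP: as GBLUP with the pedigree numerator relationship matrix."""
    return gblup_predict(y_star_train, a_mat, train_idx, val_idx, sigma2_a,
                         sigma2_e, route=route, ridge=0.0)


def evaluate(ebv, y_star_val, h2: float) -> dict:
    """Fold metrics: r(EBV, y*), realized accuracy r / sqrt(h2), and the
    slope of regressing y* on EBV.  h2 <= 0 leaves accuracy undefined
    (NaN), mirroring traits whose heritability is estimated at zero."""
    ebv = np.asarray(ebv, dtype=float)
    y = np.asarray(y_star_val, dtype=float)
    if len(ebv) != len(y):
        raise DataError("EBV and validation phenotypes differ in length")
    if len(y) < 3:
        raise DataError("need at least 3 validation animals")
    v = ebv.var()
    if not np.isfinite(v) or v == 0.0:
        return {"r": float("nan"), "accuracy": float("nan"),
                "slope": float("nan"), "degenerate": True}
    r = float(np.corrcoef(ebv, y)[0, 1])
    acc = r / np.sqrt(h2) if h2 > 0 else float("nan")
    c = np.cov(y, ebv)
    slope = float(c[0, 1] / c[1, 1])
    return {"r": r, "accuracy": acc, "slope": slope, "degenerate": False}


@dataclass
class PredictionReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: pd.DataFrame       # columns: method, fold, r, accuracy, slope
    h2: float
    k: int

    def aggregate(self) -> pd.DataFrame:
        """Mean +/- SE (sd / sqrt(k)) of each metric across folds."""
        rows = []
        for method, grp in self.per_fold.groupby("method"):
            row = {"method": method}
            for col in ("r", "accuracy", "slope"):
                vals = grp[col].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{col}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                                    if len(vals) > 1 else np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"{self.k}-fold sire-family cross-validation (h2 = {self.h2:.3f})",
            "=" * 62,
            f"{'method':<10}{'r':>12}{'accuracy':>16}{'slope':>14}",
        ]
        for _, row in agg.iterrows():
            lines.append(
                f"{row['method']:<10}"
                f"{row['r_mean']:>7.3f}+/-{row['r_se']:.3f}"
                f"{row['accuracy_mean']:>9.3f}+/-{row['accuracy_se']:.3f}"
                f"{row['slope_mean']:>8.3f}+/-{row['slope_se']:.3f}"
            )
        return "\n".join(lines)


def cross_validate(y_star, folds: FoldAssignment, h2: float,
                   sigma2_a: float, sigma2_e: float,
                   grm: RelationshipMatrix | None = None,
                   a_mat: RelationshipMatrix | None = None,
                   genotypes: GenotypeMatrix | None = None,
                   methods=("gblup",), chain: ChainConfig | None = None,
                   seed: int = 0, **bayes_kwargs) -> PredictionReport:
    """Run k-fold cross-validation for the requested methods.

    ``y_star`` must be ordered like the fold assignment's animals (and the
    relationship matrices / genotype rows).  Variance components and h2
    come from the full-data REML fit.
    """
    y = np.asarray(y_star, dtype=float)
    n = len(y)
    for mat, name in ((grm, "gblup"), (a_mat, "pblup")):
        if name in methods and mat is None:
            raise ConfigError(f"{name} requested but no relationship matrix given")
    if "bayescpi" in methods and genotypes is None:
        raise ConfigError("bayescpi requested but no genotypes given")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigError(f"unknown methods: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    chain_seeds = rng.integers(0, 2**31 - 1, size=folds.k)
    rows = []
    for fold in range(1, folds.k + 1):
        val_idx = folds.indices(fold)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        y_train = y[train_idx]
        for method in methods:
            if method == "gblup":
                ebv = gblup_predict(y_train, grm, train_idx, val_idx,
                                    sigma2_a, sigma2_e)
            elif method == "pblup":
                ebv = pblup_predict(y_train, a_mat, train_idx, val_idx,
                                    sigma2_a, sigma2_e)
            else:
                kw = {"sigma2_u_hat": sigma2_a, "sigma2_0_hat": sigma2_e,
                      **bayes_kwargs}
                model = BayesCPi(y_train, genotypes.subset_animals(train_idx),
                                 **kw)
                cc = chain or ChainConfig()
                res = model.fit(ChainConfig(cc.n_iter, cc.burn_in, cc.thin,
                                            int(chain_seeds[fold - 1])))
                ebv = res.predict(genotypes.subset_animals(val_idx))
            metrics = evaluate(ebv, y[val_idx], h2)
            rows.append({"method": method, "fold": fold, **metrics})
    return PredictionReport(per_fold=pd.DataFrame(rows), h2=h2, k=folds.k)
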