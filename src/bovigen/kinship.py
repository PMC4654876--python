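"""Genomic (VanRaden method 1) and pedigree (tabular method) relationship
matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, RelationshipMatrix
from .exceptions import DataError


def grm_vanraden1(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix G = ZZ' / sum_j 2 p_j (1 - p_j).

    Z holds allele-frequency-centred dosages x_ij - 2 p_j with p_j estimated
    from the analysed sample, so every row of G sums to zero exactly and the
    mean diagonal is ~1 for a sample in Hardy-Weinberg proportions.  G is
    rank-deficient by construction; use ``RelationshipMatrix.with_ridge``
    before inverting.
    """
    if genotypes.has_missing:
        raise DataError("GRM requires complete dosages; run QC/imputation first")
    X = genotypes.dosages
    p = X.mean(axis=0) / 2.0
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise DataError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = X - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, kind="genomic", animal_ids=genotypes.animal_ids)


def a_matrix(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` needs columns animal_id, sire_id and (optionally) dam_id;
    unknown parents (NA or absent from animal_id) are treated as unrelated
    founders.  Half-sibs sharing only a sire get 0.25.  Parents referenced
    but not listed as animals are appended as founder rows internally and
    dropped from the returned matrix.
    """
    ped = pedigree.copy()
    if "dam_id" not in ped.columns:
        ped["dam_id"] = pd.NA
    ids = list(ped["animal_id"])
    if len(set(ids)) != len(ids):
        raise DataError("duplicate animal_id in pedigree")
    known = set(ids)
    parents = set()
    for col in ("sire_id", "dam_id"):
        parents.update(x for x in ped[col] if pd.notna(x))
    extra = sorted(parents - known)

    order = _topological_order(ped, extra)
    pos = {a: i for i, a in enumerate(order)}
    sire = {r.animal_id: (r.sire_id if pd.notna(r.sire_id) else None)
            for r in ped.itertuples()}
    dam = {r.animal_id: (r.dam_id if pd.notna(r.dam_id) else None)
           for r in ped.itertuples()}

    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = sire.get(animal), dam.get(animal)
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        a_sd = A[si, di] if (si is not None and di is not None) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        vals = np.zeros(i)
        if si is not None:
            vals += 0.5 * A[:i, si]
        if di is not None:
            vals += 0.5 * A[:i, di]
        A[i, :i] = vals
        A[:i, i] = vals

    keep = [pos[a] for a in ids]
    return RelationshipMatrix(A[np.ix_(keep, keep)], kind="pedigree",
                              animal_ids=np.asarray(ids))


def _topological_order(ped: pd.DataFrame, extra_founders: list) -> list:
    """Parents-before-offspring ordering; raises on pedigree cycles."""
    children = {r.animal_id: [p for p in (r.sire_id, r.dam_id) if pd.notna(p)]
                for r in ped.itertuples()}
    order = list(extra_founders)
    placed = set(extra_founders)
    remaining = [a for a in ped["animal_id"]]
    while remaining:
        progress = False
        deferred = []
        for a in remaining:
            if all(p in placed or p not in children for p in children.get(a, [])):
                # a parent that is itself unlisted is a founder
                for p in children.get(a, []):
                    if p not in placed:
                        order.append(p)
                        placed.add(p)
                order.append(a)
                placed.add(a)
                progress = True
            else:
                deferred.append(a)
        if not progress:
            raise DataError(f"pedigree contains a cycle involving: {deferred[:5]}")
        remaining = deferred
    return order
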