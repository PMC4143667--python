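"""Core data containers: long-format phenotype tables and genotype matrices.

The phenotype table is a plain :class:`pandas.DataFrame` in long format, one
row per subject-examination, with two blood-pressure traits and the
time-varying covariates used by the mixed model.  :class:`GenotypeMatrix`
wraps an additive-dosage array (0/1/2 copies of the minor allele, ``NaN`` for
a missing call) together with per-SNP metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: Required columns of a long-format phenotype table.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "exam",
    "time",
    "sbp",
    "dbp",
    "baseline_age",
    "sex",
    "medication",
    "smoking",
)

#: Columns of the per-SNP metadata frame inside :class:`GenotypeMatrix`.
SNP_META_COLUMNS = ("snp_id", "chrom", "pos", "minor_allele", "major_allele")


def validate_phenotypes(df: pd.DataFrame) -> None:
    """Check the structural invariants of a long-format phenotype table.

    Raises
    ------
    InvalidParameterError
        If required columns are absent, examination times decrease within a
        subject, the first examination is not at time zero, or baseline age /
        sex vary within a subject.
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"phenotype table missing columns: {missing}")
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("exam")
        t = g["time"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            raise InvalidParameterError(f"subject {sid}: time decreases across exams")
        if abs(t[0]) > 1e-12:
            raise InvalidParameterError(f"subject {sid}: first exam time is {t[0]}, not 0")
        for col in ("baseline_age", "sex"):
            if g[col].nunique(dropna=True) > 1:
                raise InvalidParameterError(f"subject {sid}: {col} varies across exams")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_subjects, n_snps)
        Values in {0, 1, 2} counting minor-allele copies; ``NaN`` = missing.
    subjects : sequence of subject identifiers (length n_subjects).
    snps : DataFrame with columns ``snp_id, chrom, pos, minor_allele,
        major_allele`` (one row per SNP, unique snp_id).
    """

    dosages: np.ndarray
    subjects: np.ndarray
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.subjects = np.asarray(self.subjects)
        if self.dosages.ndim != 2:
            raise InvalidParameterError("dosages must be a 2-D (subjects x snps) array")
        n_subj, n_snp = self.dosages.shape
        if len(self.subjects) != n_subj:
            raise InvalidParameterError("subjects length does not match dosage rows")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise InvalidParameterError(f"snp metadata missing columns: {missing_cols}")
        if len(self.snps) != n_snp:
            raise InvalidParameterError("snp metadata rows do not match dosage columns")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].tolist()
            raise InvalidParameterError(f"duplicate snp_ids: {dup}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise InvalidParameterError("dosages must be in {0, 1, 2} or NaN")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def dosage_series(self, snp_id) -> pd.Series:
        """Dosages for one SNP as a Series indexed by subject id."""
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return pd.Series(self.dosages[:, idx[0]], index=self.subjects, name=snp_id)

    def subset(self, subject_mask=None, snp_mask=None) -> "GenotypeMatrix":
        """Boolean-mask subsetting along either axis (copies)."""
        sm = np.ones(self.n_subjects, bool) if subject_mask is None else np.asarray(subject_mask, bool)
        km = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        return GenotypeMatrix(
            self.dosages[np.ix_(sm, km)].copy(),
            self.subjects[sm].copy(),
            self.snps.loc[km].reset_index(drop=True).copy(),
        )
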