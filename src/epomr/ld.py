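"""LD reference: an allele-aligned correlation matrix over a variant panel."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LDMatrix:
    """Square dosage correlation matrix for a regional variant panel.

    ``var_dosage`` (sample dosage variances, ddof=1) is carried when the
    matrix is computed from genotypes; with it, summary-based joint fits
    reproduce individual-level regression exactly. ``pos`` enables the LD
    window in the conditional-selection stage.
    """

    variant_ids: list[str]
    r: np.ndarray
    freqs: np.ndarray | None = None
    n_ref: int | None = None
    var_dosage: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variant_ids)
        if self.r.shape != (m, m):
            raise ValueError("LD matrix shape does not match the variant panel")
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        if not np.allclose(self.r, self.r.T, atol=tol):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=tol):
            raise ValueError("LD matrix diagonal is not 1")
        if np.linalg.eigvalsh(self.r).min() < -tol * len(self.variant_ids):
            raise ValueError("LD matrix is not positive semi-definite")

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        return np.array([lookup[i] for i in ids], dtype=int)


def ld_from_genotypes(genotypes) -> LDMatrix:
    """Exact in-sample LD (correlation, frequencies, variances) from dosages."""
    dos = genotypes.dosages.astype(float)
    return LDMatrix(
        variant_ids=list(genotypes.panel["SNP"]),
        r=np.corrcoef(dos.T),
        freqs=genotypes.sample_freqs(),
        n_ref=genotypes.n_samples,
        var_dosage=dos.var(axis=0, ddof=1),
        pos=genotypes.panel["POS"].to_numpy(),
    )


def write_ld(ld: LDMatrix, path) -> None:
    """Whitespace-delimited square matrix with a header row of variant ids."""
    with open(path, "w") as fh:
        fh.write(" ".join(ld.variant_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_ld(path, panel: pd.DataFrame | None = None, n_ref: int | None = None) -> LDMatrix:
    """Read the square text format; frequencies/positions come from ``panel``."""
    with open(path) as fh:
        ids = fh.readline().split()
        r = np.loadtxt(fh)
    r = np.atleast_2d(r)
    freqs = pos = None
    if panel is not None:
        sub = panel.set_index("SNP").loc[ids]
        freqs = sub["FREQ_A1"].to_numpy(float)
        pos = sub["POS"].to_numpy()
    return LDMatrix(variant_ids=ids, r=r, freqs=freqs, n_ref=n_ref, pos=pos)
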