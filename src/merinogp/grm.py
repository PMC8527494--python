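"""VanRaden genomic relationship matrix (method 1).

G = W W' / (2 * sum_f p_f (1 - p_f)), where column f of W is the dosage of
the counted allele centered by twice its sample frequency. G is invariant
to which allele is counted at each marker: flipping dosage d -> 2 - d and
p -> 1 - p negates the column of W and leaves both W W' and the denominator
unchanged.
"""

from __future__ import annotations

import numpy as np

from merinogp.containers import GRM, GenotypeMatrix


def allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per marker, p_f = mean(dosage_f) / 2.

    Requires a complete (imputed) matrix; frequencies come from the
    analyzed sample itself, the standard choice when no base population
    is defined.
    """
    if gm.n_markers == 0 or gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if not gm.is_complete():
        raise ValueError("genotype matrix has missing entries; impute first")
    return gm.dosages.mean(axis=0) / 2.0


def center_dosages(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """W = dosage - 2p per column (the additive-effect design matrix)."""
    return np.asarray(dosages, dtype=float) - 2.0 * np.asarray(freqs, dtype=float)


def vanraden_grm(
    gm: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    drop_monomorphic: bool = True,
) -> GRM:
    """Build the genomic relationship matrix from a complete dosage matrix.

    Markers with p(1-p) = 0 contribute nothing to W W' when centered at
    their own frequency but would still not belong in the denominator;
    with ``drop_monomorphic`` they are excluded from both, otherwise their
    presence raises.
    """
    if freqs is None:
        freqs = allele_freqs(gm)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (gm.n_markers,):
        raise ValueError("frequency vector length mismatch")
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if not gm.is_complete():
        raise ValueError("genotype matrix has missing entries; impute first")

    het = freqs * (1.0 - freqs)
    poly = het > 0
    if not poly.any():
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    if not poly.all():
        if not drop_monomorphic:
            raise ValueError(
                f"{int((~poly).sum())} monomorphic markers present and drop_monomorphic=False"
            )
        dosages = gm.dosages[:, poly]
        freqs_used = freqs[poly]
    else:
        dosages = gm.dosages
        freqs_used = freqs

    w = center_dosages(dosages, freqs_used)
    denom = 2.0 * float(freqs_used * (1.0 - freqs_used) @ np.ones_like(freqs_used))
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0  # clean up round-off asymmetry
    return GRM(g, list(gm.individual_ids), denom)


def write_grm_tsv(grm: GRM, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(grm.individual_ids) + "\n")
        for i, iid in enumerate(grm.individual_ids):
            fh.write(iid + "\t" + "\t".join(f"{v:.10g}" for v in grm.matrix[i]) + "\n")


def read_grm_tsv(path) -> GRM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    ids = [str(i) for i in df.index]
    # the TSV does not carry the scaling denominator
    return GRM((mat + mat.T) / 2.0, ids, float("nan"))
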