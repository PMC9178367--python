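"""Plain-text persistence for interaction matrices and ensembles.

Matrices are written as delimited text (one row per line); each matrix or
ensemble gets a sidecar ``.meta`` file of ``key: value`` lines recording
the generating parameters so a written ensemble can be reloaded with its
provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .interactions import (
    CommunityParams,
    CorrelationSpec,
    HabitatEnsemble,
    InteractionMatrix,
)

__all__ = ["write_matrix", "read_matrix", "write_ensemble", "read_ensemble"]

_DELIM = "\t"


def write_matrix(path, matrix: InteractionMatrix | np.ndarray, metadata: dict | None = None):
    path = Path(path)
    entries = matrix.entries if isinstance(matrix, InteractionMatrix) else np.asarray(matrix)
    np.savetxt(path, entries, delimiter=_DELIM, fmt="%.17g")
    if metadata:
        meta_path = path.with_suffix(path.suffix + ".meta")
        lines = [f"{k}: {v}" for k, v in metadata.items()]
        meta_path.write_text("\n".join(lines) + "\n")


def read_matrix(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=_DELIM, ndmin=2)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: interaction matrix must be square")
    return arr


def _read_meta(path) -> dict:
    meta = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
    return meta


def write_ensemble(directory, ensemble: HabitatEnsemble, stem: str = "habitat"):
    """Write each habitat matrix plus one ensemble-level metadata file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g, m in enumerate(ensemble.matrices):
        write_matrix(directory / f"{stem}_{g:03d}.tsv", m)
    p = ensemble.params
    spec = ensemble.spec
    meta = {
        "G": ensemble.G, "N": p.N, "c": p.c, "mu": p.mu, "sigma": p.sigma,
        "kind": spec.kind, "rho": spec.rho, "rho_nn": spec.rho_nn,
        "seed": ensemble.seed, "stem": stem,
    }
    lines = [f"{k}: {v}" for k, v in meta.items() if v is not None]
    (directory / "ensemble.meta").write_text("\n".join(lines) + "\n")


def read_ensemble(directory) -> HabitatEnsemble:
    directory = Path(directory)
    meta = _read_meta(directory / "ensemble.meta")
    G = int(meta["G"])
    stem = meta.get("stem", "habitat")
    kind = meta["kind"]
    spec = CorrelationSpec(
        kind,
        rho=float(meta["rho"]) if kind == "equicorrelated" else None,
        rho_nn=float(meta["rho_nn"]) if kind == "nn_chain" else None,
    )
    params = CommunityParams(
        N=int(meta["N"]), c=float(meta["c"]),
        mu=float(meta["mu"]), sigma=float(meta["sigma"]),
    )
    matrices = []
    for g in range(G):
        entries = read_matrix(directory / f"{stem}_{g:03d}.tsv")
        mask = entries != 0.0
        np.fill_diagonal(mask, False)
        matrices.append(InteractionMatrix(entries=entries, mask=mask))
    if kind != "independent" and G > 1:
        # shared structural mask: an entry absent everywhere is structural,
        # present anywhere means present in all habitats
        union = np.zeros_like(matrices[0].mask)
        for m in matrices:
            union |= m.mask
        matrices = [InteractionMatrix(entries=m.entries, mask=union) for m in matrices]
    seed = meta.get("seed")
    return HabitatEnsemble(matrices, spec, params,
                           seed=int(seed) if seed is not None else None)
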