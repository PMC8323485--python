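"""Readers and writers for the plain-text table formats.

Two layouts are accepted for multi-context data:

* **long** — one row per observed (individual, context) pair, with columns
  ``individual_id``, ``context``, ``response`` and one column per
  covariate; missing pairs simply have no row.
* **wide** — responses as an individuals x contexts table (missing entries
  empty or ``NA``), covariates in a separate individuals x covariates
  table.

The meta-analysis writer emits the tab-delimited format expected by
external fixed/random-effects meta-analysis tools: one row per test with
an identifier followed by alternating beta and SE per context, ``NA NA``
for unobserved contexts, plus an optional companion file of per-test
correlation matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import MultiContextData

_NA = ("", "NA", "NaN", "nan", "na")


def read_long(path, covariate_columns: list[str] | None = None) -> MultiContextData:
    """Read long-format TSV into a :class:`MultiContextData`.

    Covariates must be constant within an individual; an intercept column
    is prepended automatically if the first covariate is not already
    constant 1.
    """
    df = pd.read_csv(path, sep="\t", na_values=list(_NA), keep_default_na=True)
    required = {"individual_id", "context", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long format requires columns {sorted(required)}")
    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c not in required]
    individuals = list(dict.fromkeys(df["individual_id"].astype(str)))
    contexts = list(dict.fromkeys(df["context"].astype(str)))
    ind_pos = {v: i for i, v in enumerate(individuals)}
    ctx_pos = {v: j for j, v in enumerate(contexts)}
    responses = np.full((len(individuals), len(contexts)), np.nan)
    covs = np.full((len(individuals), len(covariate_columns)), np.nan)
    for row in df.itertuples(index=False):
        i = ind_pos[str(row.individual_id)]
        j = ctx_pos[str(row.context)]
        if not np.isnan(responses[i, j]):
            raise ValueError(
                f"{path}: duplicate row for individual {row.individual_id!r}, "
                f"context {row.context!r}"
            )
        responses[i, j] = row.response
        vals = [getattr(row, c) for c in covariate_columns]
        if np.isnan(covs[i]).all():
            covs[i] = vals
        elif not np.allclose(covs[i], vals, equal_nan=True):
            raise ValueError(
                f"{path}: covariates vary within individual {row.individual_id!r}"
            )
    covs = _with_intercept(covs)
    return MultiContextData(
        responses=responses,
        covariates=covs,
        context_labels=contexts,
        individual_ids=individuals,
    )


def read_wide(responses_path, covariates_path=None) -> MultiContextData:
    """Read wide-format tables (responses: individuals x contexts)."""
    resp = pd.read_csv(
        responses_path, sep="\t", index_col=0, na_values=list(_NA), keep_default_na=True
    )
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
        cov = cov.reindex(resp.index)
        if cov.isna().any().any():
            missing = cov.index[cov.isna().any(axis=1)].tolist()
            raise ValueError(
                f"{covariates_path}: missing covariates for individuals {missing}"
            )
        covs = _with_intercept(cov.to_numpy(dtype=float))
    else:
        covs = np.ones((resp.shape[0], 1))
    return MultiContextData(
        responses=resp.to_numpy(dtype=float),
        covariates=covs,
        context_labels=[str(c) for c in resp.columns],
        individual_ids=[str(i) for i in resp.index],
    )


def write_wide(data: MultiContextData, responses_path, covariates_path=None) -> None:
    resp = pd.DataFrame(
        data.responses, index=data.individual_ids, columns=data.context_labels
    )
    resp.index.name = "individual_id"
    resp.to_csv(responses_path, sep="\t", na_rep="NA", float_format="%.10g")
    if covariates_path is not None:
        cov = pd.DataFrame(
            data.covariates,
            index=data.individual_ids,
            columns=[f"cov{j}" for j in range(data.c)],
        )
        cov.index.name = "individual_id"
        cov.to_csv(covariates_path, sep="\t", float_format="%.10g")


def write_long(data: MultiContextData, path) -> None:
    rows = []
    obs = data.observed_mask
    for i, iid in enumerate(data.individual_ids):
        for j, ctx in enumerate(data.context_labels):
            if obs[i, j]:
                rows.append(
                    [iid, ctx, data.responses[i, j], *data.covariates[i, 1:]]
                )
    cols = ["individual_id", "context", "response"] + [
        f"cov{j}" for j in range(1, data.c)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_genotypes(path) -> pd.DataFrame:
    """Variants x individuals dosage table; first column is the variant id."""
    geno = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(geno.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: genotype dosages must be finite numbers")
    return geno


def iter_genotype_chunks(path, chunk_size: int = 1000):
    """Stream a genotype table in chunks of ``chunk_size`` variants."""
    for chunk in pd.read_csv(path, sep="\t", index_col=0, chunksize=chunk_size):
        yield chunk


# ---------------------------------------------------------------------------
# meta-analysis input format


def write_metasoft_input(path, rows, float_format: str = "%.6g") -> None:
    """Write per-context effects: ``id beta1 se1 ... betaT seT`` per line.

    ``rows`` yields ``(identifier, betas, ses)``; NaN entries are written
    as the ``NA NA`` pair.
    """
    with open(path, "w") as fh:
        for ident, betas, ses in rows:
            fields = [str(ident)]
            for b, s in zip(betas, ses):
                if np.isnan(b) or np.isnan(s):
                    fields += ["NA", "NA"]
                else:
                    fields += [float_format % b, float_format % s]
            fh.write("\t".join(fields) + "\n")


def read_metasoft_input(path):
    """Round-trip reader for :func:`write_metasoft_input`."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or len(fields) % 2 == 0:
                raise ValueError(f"{path}: malformed row {fields[:1]}")
            vals = [np.nan if f in _NA else float(f) for f in fields[1:]]
            arr = np.array(vals).reshape(-1, 2)
            out.append((fields[0], arr[:, 0].copy(), arr[:, 1].copy()))
    return out


def write_correlation_matrices(path, matrices, float_format: str = "%.6g") -> None:
    """Companion file: one whitespace-delimited t x t matrix per test."""
    with open(path, "w") as fh:
        for m in matrices:
            for row in np.asarray(m):
                fh.write(" ".join(float_format % v for v in row) + "\n")


def read_correlation_matrices(path, t: int):
    lines = [ln.split() for ln in open(path) if ln.strip()]
    if len(lines) % t:
        raise ValueError(f"{path}: line count is not a multiple of t={t}")
    mats = []
    for k in range(0, len(lines), t):
        mats.append(np.array([[float(v) for v in row] for row in lines[k : k + t]]))
    return mats


def _with_intercept(covs: np.ndarray) -> np.ndarray:
    if covs.shape[1] and np.allclose(covs[:, 0], 1.0):
        return covs
    return np.column_stack([np.ones(covs.shape[0]), covs])
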