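"""Gene-list queries against a perturbation-signature matrix.

Given a list of query genes, each perturbagen (drug treatment) is scored by
the mean signature z of the query genes: a treatment that down-regulates the
list scores strongly negative, mimicking a knock-down of those genes.
Significance comes from a size-matched permutation null: for each of
``n_perm`` draws, a random gene set of the same size is sampled without
replacement from the measured genes and scored the same way, and

    p = (1 + #{null <= observed}) / (n_perm + 1)

for direction ``down`` (mirrored for ``up``; doubled smaller tail, capped at
1, for ``two_sided``).  The add-one correction keeps p >= 1/(n_perm + 1).
Sampling is restricted to the measured gene universe, which conditions the
null on what the assay covers.  q-values are Benjamini-Hochberg across
perturbagens.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import SignatureMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("down", "up", "two_sided")


def query_gene_list(
    genes: Sequence[str],
    sig: SignatureMatrix,
    direction: str = "down",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank perturbagens by mean signature z over a query gene list.

    Returns a DataFrame with columns ``perturbagen_id, score, n_genes_used,
    p, q``, sorted ascending by score for ``down`` (descending for ``up``,
    by |score| descending for ``two_sided``), ties broken by perturbagen ID.
    Query genes absent from the matrix are dropped with a warning; duplicates
    are collapsed.  Requires ``n_perm >= 100``.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    if n_perm < 100:
        raise DataError(f"n_perm must be >= 100, got {n_perm}")

    # collapse duplicates, keep deterministic order
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(g, None)
    wanted = list(seen)
    gene_index = {g: i for i, g in enumerate(sig.gene_ids)}
    used = [g for g in wanted if g in gene_index]
    missing = [g for g in wanted if g not in gene_index]
    if not used:
        raise DataError(f"no query gene found in the signature matrix; misses: {missing}")
    if missing:
        logger.warning("dropping %d query genes absent from signatures: %s", len(missing), missing)

    Z = sig.z.to_numpy()
    # sorted row order makes the score exactly invariant to query-gene order
    rows = np.sort(np.array([gene_index[g] for g in used], dtype=int))
    m = len(rows)
    obs = Z[rows].mean(axis=0)  # per perturbagen

    rng = np.random.default_rng(seed)
    n_genes = Z.shape[0]
    # null: n_perm size-matched random gene sets, scored identically
    null = np.empty((n_perm, Z.shape[1]))
    for i in range(n_perm):
        pick = rng.choice(n_genes, size=m, replace=False)
        null[i] = Z[pick].mean(axis=0)

    le = (null <= obs).sum(axis=0)
    ge = (null >= obs).sum(axis=0)
    p_down = (1.0 + le) / (n_perm + 1.0)
    p_up = (1.0 + ge) / (n_perm + 1.0)
    if direction == "down":
        p = p_down
    elif direction == "up":
        p = p_up
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_down, p_up))

    q = stats.false_discovery_control(p, method="bh")
    df = pd.DataFrame(
        {
            "perturbagen_id": sig.perturbagen_ids,
            "score": obs,
            "n_genes_used": m,
            "p": p,
            "q": q,
        }
    )
    if direction == "down":
        key = df["score"]
    elif direction == "up":
        key = -df["score"]
    else:
        key = -df["score"].abs()
    df = df.assign(_key=key).sort_values(["_key", "perturbagen_id"]).drop(columns="_key")
    return df.reset_index(drop=True)
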