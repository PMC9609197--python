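"""Dataset-level characterization.

Batch classification collects per-molecule superclass membership into a
binary table and tallies *exact* label combinations (UpSet semantics:
each molecule counts toward exactly one combination, the full set of
labels it carries).  The combination counts are drawn as an UpSet-style
plot — count bars over a membership-dot matrix — with optional pruning
of near-empty combinations.

Compound-name resolution against the public PubChem PUG-REST service is
available but strictly opt-in (``allow_network=True``); everything else
in this module runs offline.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .elements import DEFAULT_TABLES, ElementTables
from .smiles import SmilesError
from .taxonomy import ALL_SUPERCLASSES, TaxonomyResult, classify

__all__ = [
    "BulkSummary",
    "classify_batch",
    "upset_plot",
    "resolve_name",
    "NameResolutionError",
]


@dataclass
class BulkSummary:
    """Membership table plus exact-combination counts for one dataset."""

    membership: pd.DataFrame
    intersection_counts: dict[tuple[str, ...], int]
    n_molecules: int
    n_failed: int
    failures: list[dict] = field(default_factory=list)


def classify_batch(
    smiles_list: Iterable[str], tables: ElementTables = DEFAULT_TABLES
) -> BulkSummary:
    """Classify every molecule; duplicates are kept, failures counted.

    Classification is cached per distinct string, so large batches with
    repeated molecules cost one rule evaluation per unique SMILES.
    """
    cache: dict[str, TaxonomyResult | SmilesError] = {}
    rows = []
    counts: dict[tuple[str, ...], int] = {}
    failures: list[dict] = []
    for i, smi in enumerate(smiles_list):
        hit = cache.get(smi)
        if hit is None:
            try:
                hit = classify(smi, tables)
            except SmilesError as exc:
                hit = exc
            cache[smi] = hit
        if isinstance(hit, SmilesError):
            failures.append({"index": i, "smiles": smi, "error": str(hit)})
            continue
        combo = hit.ordered_superclasses()
        counts[combo] = counts.get(combo, 0) + 1
        row = {"smiles": hit.smiles, "kingdom": hit.kingdom}
        row.update({label: int(label in hit.superclasses) for label in ALL_SUPERCLASSES})
        rows.append(row)
    membership = pd.DataFrame(
        rows, columns=["smiles", "kingdom", *ALL_SUPERCLASSES]
    )
    return BulkSummary(
        membership=membership,
        intersection_counts=counts,
        n_molecules=len(rows),
        n_failed=len(failures),
        failures=failures,
    )


def _sorted_combos(summary: BulkSummary, min_subset_size: int):
    """Descending count; ties broken by lexicographic combination label."""
    kept = [
        (combo, n)
        for combo, n in summary.intersection_counts.items()
        if n >= min_subset_size
    ]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return kept


def upset_plot(
    summary: BulkSummary,
    output_path: str | Path,
    min_subset_size: int = 1,
) -> Path:
    """Render the UpSet plot and write the plotted counts alongside.

    Combinations with fewer than ``min_subset_size`` molecules are
    dropped.  The count table backing the plot is written next to the
    image as ``<stem>_counts.csv`` so the plot contents are machine
    checkable.  Raises ``ValueError`` if nothing survives pruning.
    """
    if min_subset_size < 0:
        raise ValueError("min_subset_size must be >= 0")
    combos = _sorted_combos(summary, min_subset_size)
    if not combos:
        raise ValueError(
            "no superclass combination has at least "
            f"{min_subset_size} molecules; lower min_subset_size"
        )

    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = [lab for lab in ALL_SUPERCLASSES if any(lab in c for c, _ in combos)]
    ncombo, nlab = len(combos), len(labels)

    fig_w = max(6.0, 0.42 * ncombo + 3.2)
    fig_h = max(4.0, 0.28 * nlab + 2.6)
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(fig_w, fig_h), sharex=True,
        gridspec_kw={"height_ratios": [2.2, 1.3], "hspace": 0.06},
    )
    xs = range(ncombo)
    heights = [n for _, n in combos]
    ax_bar.bar(xs, heights, color="#30506d")
    for x, h in zip(xs, heights):
        ax_bar.annotate(str(h), (x, h), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("molecules")
    ax_bar.set_title(
        f"superclass intersections ({summary.n_molecules} molecules, "
        f"{summary.n_failed} failed)"
    )
    ax_bar.spines[["top", "right"]].set_visible(False)

    for x, (combo, _n) in enumerate(combos):
        member_ys = [labels.index(lab) for lab in combo]
        ax_mat.scatter([x] * nlab, range(nlab), s=18, color="#d5d9dd", zorder=1)
        if member_ys:
            ax_mat.scatter([x] * len(member_ys), member_ys, s=30,
                           color="#30506d", zorder=2)
            ax_mat.plot([x, x], [min(member_ys), max(member_ys)],
                        color="#30506d", lw=1.4, zorder=2)
    ax_mat.set_yticks(range(nlab))
    ax_mat.set_yticklabels(labels, fontsize=8)
    ax_mat.set_xticks([])
    ax_mat.set_xlim(-0.6, ncombo - 0.4)
    ax_mat.invert_yaxis()
    for spine in ax_mat.spines.values():
        spine.set_visible(False)

    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(output_path, bbox_inches="tight", dpi=150)
    plt.close(fig)

    counts_path = output_path.with_name(output_path.stem + "_counts.csv")
    pd.DataFrame(
        {"combination": [";".join(c) for c, _ in combos],
         "count": [n for _, n in combos]}
    ).to_csv(counts_path, index=False)
    return output_path


# ---------------------------------------------------------------------------
# optional network feature


class NameResolutionError(RuntimeError):
    pass


_PUG_REST = (
    "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/name/"
    "{name}/property/IsomericSMILES/JSON"
)
_RESOLVE_CACHE: dict[str, str] = {}


def resolve_name(name: str, allow_network: bool = False,
                 timeout: float = 15.0) -> str:
    """Resolve a compound name to its isomeric SMILES via PUG-REST.

    Off by default: raises :class:`NameResolutionError` unless
    ``allow_network=True``.  Successful lookups are cached for the
    process lifetime; failures never silently substitute a value.
    """
    if not allow_network:
        raise NameResolutionError(
            "name resolution is a network feature and is disabled; "
            "pass allow_network=True to enable it"
        )
    if not name or not name.strip():
        raise NameResolutionError("empty compound name")
    key = name.strip().lower()
    if key in _RESOLVE_CACHE:
        return _RESOLVE_CACHE[key]
    url = _PUG_REST.format(name=urllib.parse.quote(name.strip()))
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            payload = json.load(resp)
        smiles = payload["PropertyTable"]["Properties"][0]["IsomericSMILES"]
    except (urllib.error.URLError, KeyError, IndexError, ValueError) as exc:
        raise NameResolutionError(f"could not resolve {name!r}: {exc}") from exc
    _RESOLVE_CACHE[key] = smiles
    return smiles
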