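"""Sequence-variant filtering, rarefaction, and provenance attribution.

The scientific core: given an SV count table spanning months and depth
zones, attribute each target community (a month's surface sample, or a
depth zone's representative sample) to the earliest month / shallowest
zone at which each of its SVs was first detected. Communities are
partitioned on either a read-count basis (weight = reads in the target)
or a richness basis (weight = 1 per present SV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .table import SVTable, SampleMetadata, TaxonomyMap

#: Phytoplankton higher taxa retained by default. Dinoflagellates (largely
#: heterotrophic / undescribed) and flagged heterotrophs are then removed.
DEFAULT_INCLUDE_GROUPS = frozenset(
    {"Archaeplastida", "Cryptophyta", "Haptophyta", "Chlorarachniophyta", "Heterokontophyta"}
)
DEFAULT_EXCLUDE_TOKENS = frozenset({"Dinophyceae", "Dinoflagellata"})


def filter_phytoplankton(
    table: SVTable,
    tax: TaxonomyMap,
    include_groups: frozenset[str] | set[str] = DEFAULT_INCLUDE_GROUPS,
    exclude_tokens: frozenset[str] | set[str] = DEFAULT_EXCLUDE_TOKENS,
    exclude_heterotrophs: bool = True,
) -> SVTable:
    """Retain SVs whose lineage names a phytoplankton group, then drop decoys.

    An SV is retained iff its lineage contains at least one include token,
    and afterwards removed if its lineage contains any exclude token or
    (when ``exclude_heterotrophs``) it is annotated as a heterotroph.
    The sample set is unchanged.
    """
    if not include_groups:
        raise ValueError("include_groups must be non-empty")
    tax.check_covers(table)
    keep = []
    for sv in table.sv_ids:
        lineage = tax.lineage(sv)
        if not any(tok in lineage for tok in include_groups):
            continue
        if any(tok in lineage for tok in exclude_tokens):
            continue
        if exclude_heterotrophs and tax.trophic(sv) == "heterotroph":
            continue
        keep.append(sv)
    return SVTable(table.counts.loc[keep])


def rarefy(
    table: SVTable,
    depth: int,
    seed: int | np.random.Generator,
    drop_below: bool = False,
) -> SVTable:
    """Subsample every sample to ``depth`` reads, uniformly without replacement.

    Each sample's reads are treated as a finite pool (one item per read);
    exactly ``depth`` are drawn without replacement, i.e. per-SV rarefied
    counts follow the multivariate hypergeometric distribution. Counts stay
    integers and never exceed the originals. Samples with fewer than
    ``depth`` reads are an error unless ``drop_below``, in which case they
    are removed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    totals = table.sample_totals()
    low = totals.index[totals < depth].tolist()
    if low and not drop_below:
        raise ValueError(
            f"samples below rarefaction depth {depth}: {low}; "
            "pass drop_below=True to discard them"
        )
    cols = [s for s in table.sample_ids if s not in low]
    if not cols:
        raise ValueError(f"all samples are below rarefaction depth {depth}")
    out = {}
    for s in cols:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    return SVTable(pd.DataFrame(out, index=table.counts.index, columns=cols))


def presence(table: SVTable, sample_ids: Sequence[str]) -> pd.Series:
    """Boolean per-SV presence: summed count over ``sample_ids`` > 0."""
    if len(sample_ids) == 0:
        return pd.Series(False, index=table.counts.index)
    return table.counts.loc[:, list(sample_ids)].sum(axis=1) > 0


def first_detection(
    table: SVTable,
    order: Sequence[str],
    selector: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Earliest label (in ``order``) at which each SV is present.

    ``selector`` maps each label to its (disjoint) sample group. SVs absent
    from every group are omitted from the result.
    """
    if len(order) == 0:
        raise ValueError("order must be non-empty")
    if len(set(order)) != len(order):
        raise ValueError("order labels must be unique")
    seen: set[str] = set()
    for label in order:
        group = set(selector[label])
        if group & seen:
            raise ValueError(f"sample groups must be disjoint; overlap at {label!r}")
        seen |= group
    origin: dict[str, str] = {}
    for label in order:
        pres = presence(table, list(selector[label]))
        for sv in table.counts.index[pres]:
            origin.setdefault(sv, label)
    return origin


@dataclass
class AttributionResult:
    """Decomposition of one target community by origin label.

    ``origins`` maps each origin (a label preceding or equal to ``target``
    in the configured order) to its fraction of the target community.
    Fractions sum to 1 for a non-empty target; an empty target community is
    reported with empty ``origins`` and status ``"empty"``.
    """

    basis: str
    target: str
    origins: dict[str, float] = field(default_factory=dict)
    status: str = "ok"

    def fraction(self, origin: str) -> float:
        return self.origins.get(origin, 0.0)

    def new_fraction(self) -> float:
        """Fraction first detected in the target itself (allochthonous share)."""
        return self.origins.get(self.target, 0.0)


def _attribute(
    table: SVTable,
    order: Sequence[str],
    selector: Mapping[str, Sequence[str]],
    basis: str,
) -> list[AttributionResult]:
    if basis not in ("reads", "richness"):
        raise ValueError(f"basis must be 'reads' or 'richness', got {basis!r}")
    origin = first_detection(table, order, selector)
    results = []
    for target in order:
        samples = list(selector[target])
        if samples:
            counts = table.counts.loc[:, samples].sum(axis=1)
        else:
            counts = pd.Series(0, index=table.counts.index)
        present = counts.index[counts > 0]
        if len(present) == 0:
            results.append(AttributionResult(basis, target, {}, status="empty"))
            continue
        if basis == "reads":
            weights = counts.loc[present].astype(float)
        else:
            weights = pd.Series(1.0, index=present)
        total = float(weights.sum())
        fractions: dict[str, float] = {}
        for sv, w in weights.items():
            fractions[origin[sv]] = fractions.get(origin[sv], 0.0) + float(w) / total
        results.append(AttributionResult(basis, target, fractions))
    return results


def attribute_temporal(
    table: SVTable,
    meta: SampleMetadata,
    months: Sequence[str],
    basis: str = "reads",
    zone: str = "surface",
    fraction: str | None = None,
) -> list[AttributionResult]:
    """Partition each month's community by the month of first detection.

    Samples are restricted to one layer (default the surface layer) and,
    when given, one size fraction, mirroring a month-over-month turnover
    analysis run on the shallow bottle samples only.
    """
    meta.check_covers(table)
    selector = {
        m: [s for s in meta.select(month=m, zone=zone, fraction=fraction) if s in table.counts.columns]
        for m in months
    }
    return _attribute(table, months, selector, basis)


def attribute_vertical(
    table: SVTable,
    meta: SampleMetadata,
    zones: Sequence[str] = ("surface", "mesopelagic", "bathypelagic", "abyssopelagic"),
    basis: str = "reads",
    month: str | None = None,
    fraction: str | None = None,
    representative: Mapping[str, Sequence[str]] | None = None,
) -> list[AttributionResult]:
    """Partition each zone's community by the shallowest zone of first detection.

    Samples are restricted to one month and size fraction, one
    representative sample per zone. ``representative`` can override the
    zone -> sample mapping, e.g. to substitute a 300 m sample where a
    500 m mesopelagic sample is unavailable.
    """
    meta.check_covers(table)
    if representative is not None:
        selector = {z: list(representative[z]) for z in zones}
    else:
        selector = {
            z: [s for s in meta.select(month=month, zone=z, fraction=fraction) if s in table.counts.columns]
            for z in zones
        }
    return _attribute(table, zones, selector, basis)


def representative_svs(
    table: SVTable,
    threshold: float = 0.05,
    scope: Sequence[str] | None = None,
) -> pd.DataFrame:
    """SVs reaching ``threshold`` relative abundance in at least one sample.

    The comparison is inclusive (>=). Returns a frame indexed by sv_id with
    the maximal within-sample relative abundance and the sample achieving
    it, for the samples in ``scope`` (default: all).
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    scope = list(scope) if scope is not None else table.sample_ids
    if not scope:
        raise ValueError("scope must contain at least one sample")
    sub = table.counts.loc[:, scope].astype(float)
    totals = sub.sum(axis=0)
    nonzero = totals.index[totals > 0]
    rel = sub.loc[:, nonzero] / totals.loc[nonzero]
    if rel.shape[1] == 0:
        return pd.DataFrame(columns=["max_relative_abundance", "argmax_sample"])
    mx = rel.max(axis=1)
    hit = mx.index[mx >= threshold]
    return pd.DataFrame(
        {
            "max_relative_abundance": mx.loc[hit],
            "argmax_sample": rel.loc[hit].idxmax(axis=1),
        }
    )


@dataclass(frozen=True)
class VerticalPattern:
    """Vertical occurrence class of one SV, with its raw zone profile.

    Patterns: ``P1_surface_to_deep`` — present in the epipelagic (surface
    layer included) and reaching the bathypelagic or abyssopelagic;
    ``P2_epipelagic_only`` — present in the epipelagic but not reaching
    bathy/abyssopelagic (an epi+mesopelagic profile also falls here, and
    can be re-binned from ``zones_present``); ``P3_deep_only`` — absent
    from the epipelagic, present at mesopelagic depth or below.
    """

    sv_id: str
    pattern: str
    zones_present: tuple[str, ...]


def classify_vertical_patterns(
    table: SVTable,
    meta: SampleMetadata,
    month: str | None = None,
    fraction: str | None = None,
) -> list[VerticalPattern]:
    """Classify every SV present in scope into one of three vertical patterns."""
    meta.check_covers(table)
    zone_samples = {
        z: [s for s in meta.select(month=month, zone=z, fraction=fraction) if s in table.counts.columns]
        for z in ("surface", "epipelagic", "mesopelagic", "bathypelagic", "abyssopelagic")
    }
    pres = {z: presence(table, ss) for z, ss in zone_samples.items()}
    out = []
    for sv in table.sv_ids:
        zones_present = tuple(z for z in pres if pres[z][sv])
        if not zones_present:
            continue
        epi = pres["surface"][sv] or pres["epipelagic"][sv]
        deep = pres["bathypelagic"][sv] or pres["abyssopelagic"][sv]
        if epi and deep:
            pattern = "P1_surface_to_deep"
        elif epi:
            pattern = "P2_epipelagic_only"
        else:
            pattern = "P3_deep_only"
        out.append(VerticalPattern(sv, pattern, zones_present))
    return out


def shared_unique(
    table: SVTable,
    groups: Mapping[str, Sequence[str]],
) -> dict[frozenset[str], list[str]]:
    """Partition SVs by the exact set of groups in which they are present.

    Every SV present in at least one group lands in exactly one membership
    class (the frozenset of group labels containing it); class sizes sum to
    the number of present SVs.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    pres = {g: presence(table, list(groups[g])) for g in labels}
    out: dict[frozenset[str], list[str]] = {}
    for sv in table.sv_ids:
        member = frozenset(g for g in labels if pres[g][sv])
        if member:
            out.setdefault(member, []).append(sv)
    return out


def attribution_frame(results: Sequence[AttributionResult]) -> pd.DataFrame:
    """Flatten attribution results to a tidy frame (target, origin, basis, fraction)."""
    rows = []
    for r in results:
        if not r.origins:
            rows.append({"target": r.target, "origin": np.nan, "basis": r.basis, "fraction": np.nan})
        for origin, frac in r.origins.items():
            rows.append({"target": r.target, "origin": origin, "basis": r.basis, "fraction": frac})
    return pd.DataFrame(rows, columns=["target", "origin", "basis", "fraction"])
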