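"""Dual-method species consensus.

Species calls from two independent assignment strategies — a best-hit
aligner (percent identity + e-value) and a Bayesian-confidence classifier
(bootstrap posterior) — are cross-compared per ASV.  A call is *definitive*
only when both methods name the identical species.  Labels are normalised
before comparison (whitespace, case, and the provisional-genus bracket
convention: "[Clostridium] cocleatum" matches "Clostridium cocleatum").
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusCall:
    asv_id: str
    definitive: bool
    species: str | None
    method1_species: str | None
    method2_species: str | None


def normalize_species(label: str | None) -> str | None:
    """Canonical form for comparison; None for unassigned labels."""
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return None
    s = re.sub(r"\s+", " ", str(label)).strip()
    if not s or s.lower() in {"unassigned", "unclassified", "na", "nan"}:
        return None
    return s.replace("[", "").replace("]", "").casefold()


def _as_species_map(table) -> dict[str, str | None]:
    if isinstance(table, dict):
        return dict(table)
    df = pd.DataFrame(table)
    cols = {c.lower(): c for c in df.columns}
    if "asv_id" not in cols or "species" not in cols:
        raise ConsensusError("assignment table needs asv_id and species columns")
    ids = df[cols["asv_id"]].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ConsensusError(f"duplicate ASV {dup!r} in assignment table")
    return dict(zip(ids, df[cols["species"]]))


def consensus_species(a, b) -> tuple[list[ConsensusCall], dict[str, int]]:
    """Cross-compare two species-assignment tables.

    Returns per-ASV calls for ASVs assigned by both methods, plus summary
    counts: ``n_agree``, ``n_disagree`` (both assigned), and
    ``n_single_method`` (assigned by exactly one).
    """
    ma, mb = _as_species_map(a), _as_species_map(b)
    shared = sorted(set(ma) | set(mb))
    if not (set(ma) & set(mb)):
        raise ConsensusError("assignment tables share no ASVs")
    calls = []
    n_agree = n_disagree = n_single = 0
    for asv in shared:
        sa = normalize_species(ma.get(asv))
        sb = normalize_species(mb.get(asv))
        if sa is not None and sb is not None:
            definitive = sa == sb
            n_agree += definitive
            n_disagree += not definitive
            calls.append(ConsensusCall(
                asv_id=asv, definitive=definitive,
                species=sa if definitive else None,
                method1_species=sa, method2_species=sb))
        elif sa is not None or sb is not None:
            n_single += 1
            calls.append(ConsensusCall(asv_id=asv, definitive=False,
                                       species=None, method1_species=sa,
                                       method2_species=sb))
    summary = {"n_agree": n_agree, "n_disagree": n_disagree,
               "n_single_method": n_single}
    return calls, summary


def genus_level_consistency(calls: list[ConsensusCall],
                            taxonomy: pd.DataFrame | dict) -> pd.DataFrame:
    """Per genus: do all of its definitive ASVs name one species?

    Status is ``consistent`` (>=1 definitive call, all identical),
    ``inconsistent`` (definitive calls disagree), or ``no-evidence``
    (no definitive call in the genus).
    """
    if isinstance(taxonomy, pd.DataFrame):
        genus_of = taxonomy["genus"].to_dict()
    else:
        genus_of = dict(taxonomy)
    per_genus: dict[str, set[str]] = {}
    for g in set(genus_of.values()):
        per_genus[str(g)] = set()
    for c in calls:
        g = str(genus_of.get(c.asv_id, "unclassified"))
        per_genus.setdefault(g, set())
        if c.definitive and c.species is not None:
            per_genus[g].add(c.species)
    rows = []
    for g in sorted(per_genus):
        species = per_genus[g]
        if not species:
            status = "no-evidence"
            sp = ""
        elif len(species) == 1:
            status = "consistent"
            sp = next(iter(species))
        else:
            status = "inconsistent"
            sp = ";".join(sorted(species))
        rows.append({"genus": g, "status": status, "species": sp})
    return pd.DataFrame(rows).set_index("genus")


def calls_to_frame(calls: list[ConsensusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"asv_id": c.asv_id, "definitive": c.definitive,
          "species": c.species or "",
          "method1_species": c.method1_species or "",
          "method2_species": c.method2_species or ""} for c in calls]
    ).set_index("asv_id")
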