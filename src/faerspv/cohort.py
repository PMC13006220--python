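"""Target-drug cohort construction and cardiac-event extraction.

Given linked case bundles, this module (1) matches reports to one of the
seven compound inhaled long-acting bronchodilator products by normalized
name search over ``drugname``/``prod_ai`` restricted to the primary-suspect
(PS) role, (2) applies each product's market-entry search window, (3) maps
reaction PTs to their primary System Organ Class with a MedDRA-style
dictionary, and (4) extracts the cardiac-adverse-event (CAE) analysis set:
reports with at least one PT whose SOC is Cardiac disorders.

The shipped PT->SOC dictionary (``data/meddra_mock.tsv``) is a small
synthetic stand-in with invented codes — real MedDRA is licensed and cannot
be redistributed. A licensed MedDRA export with the same four columns can be
dropped in via :func:`load_meddra`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .faers_io import CaseBundle, DrugRecord

logger = logging.getLogger(__name__)

CARDIAC_SOC = "Cardiac disorders"
SEARCH_CUTOFF_QUARTER: Tuple[int, int] = (2024, 3)

#: FDA outcome codes ordered from most to least severe; a case's outcome is
#: summarised by the most severe code it carries.
SEVERITY_ORDER: Tuple[str, ...] = ("DE", "LT", "DS", "CA", "HO", "RI", "OT")
_SEVERITY_RANK = {code: i for i, code in enumerate(SEVERITY_ORDER)}

PRODUCT_IDS = ("FA", "FG", "IG", "OT", "VU", "BGF", "FUV")


@dataclass(frozen=True)
class DrugDictionaryEntry:
    product_id: str
    component_class: str  # "LABA/LAMA" or "ICS/LABA/LAMA"
    generic_names: Tuple[str, ...]
    brand_names: Tuple[str, ...]
    search_start_quarter: Tuple[int, int]


@dataclass
class MeddraMap:
    """Case-insensitive PT -> (pt_code, soc_name, soc_code) lookup."""

    _map: Dict[str, Tuple[str, str, str]]

    def lookup(self, pt: str) -> Optional[Tuple[str, str, str]]:
        return self._map.get(pt.strip().lower())

    def soc(self, pt: str) -> Optional[str]:
        hit = self.lookup(pt)
        return hit[1] if hit else None

    def __len__(self) -> int:
        return len(self._map)


@dataclass
class CAECase:
    """A target-drug report containing at least one cardiac PT."""

    bundle: CaseBundle
    product_id: str
    cae_pts: List[str]
    other_pts: List[str]
    unmapped_pts: List[str]
    most_severe_outcome: Optional[str]
    matched_drug_seqs: List[int] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.bundle.primaryid


def _parse_quarter(raw: str) -> Tuple[int, int]:
    m = re.match(r"^(\d{4})\s*Q([1-4])$", raw.strip(), flags=re.IGNORECASE)
    if not m:
        raise ValueError(f"bad quarter spec: {raw!r}")
    return (int(m.group(1)), int(m.group(2)))


def _bundled(name: str) -> Path:
    return Path(str(resources.files("faerspv.data").joinpath(name)))


def load_drug_dictionary(path=None) -> List[DrugDictionaryEntry]:
    """Load the product dictionary (TSV); defaults to the bundled seven products."""
    path = _bundled("drug_dictionary.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for rec in df.to_dict("records"):
        entries.append(
            DrugDictionaryEntry(
                product_id=rec["product_id"].strip(),
                component_class=rec["component_class"].strip(),
                generic_names=tuple(
                    n.strip() for n in rec["generic_names"].split(";") if n.strip()
                ),
                brand_names=tuple(n.strip() for n in rec["brand_names"].split(";") if n.strip()),
                search_start_quarter=_parse_quarter(rec["start_quarter"]),
            )
        )
    return entries


def load_meddra(path=None) -> MeddraMap:
    """Load a PT->SOC map (TSV: pt_name, pt_code, soc_name, soc_code)."""
    path = _bundled("meddra_mock.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = {
        rec["pt_name"].strip().lower(): (
            rec["pt_code"].strip(),
            rec["soc_name"].strip(),
            rec["soc_code"].strip(),
        )
        for rec in df.to_dict("records")
    }
    return MeddraMap(mapping)


_PUNCT_RE = re.compile(r"[^A-Z0-9/]+")


def normalize_name(raw: Optional[str]) -> str:
    """Uppercase; collapse punctuation (except ``/``) to single spaces; strip."""
    if not raw:
        return ""
    return _PUNCT_RE.sub(" ", raw.upper()).strip()


def _entry_match_score(drug: DrugRecord, entry: DrugDictionaryEntry) -> int:
    """Number of matched components (0 = no match).

    A record matches if any normalized generic/brand name is a substring of
    the normalized drugname or prod_ai, or if every component of a generic
    name appears as a substring of one of those fields regardless of order.
    The score is the component count of the best-matching name, so that a
    triple-combination name outranks the dual product nested inside it.
    """
    fields = [normalize_name(drug.drugname), normalize_name(drug.prod_ai)]
    fields = [f for f in fields if f]
    if not fields:
        return 0
    best = 0
    for name in entry.generic_names + entry.brand_names:
        norm = normalize_name(name)
        if not norm:
            continue
        components = [c.strip() for c in norm.split("/") if c.strip()]
        for f in fields:
            if norm in f or all(c in f for c in components):
                best = max(best, len(components))
    return best


@lru_cache(maxsize=16384)
def _cached_candidates(
    drugname: str, prod_ai: Optional[str], dictionary: Tuple[DrugDictionaryEntry, ...]
) -> Tuple[str, ...]:
    probe = DrugRecord(drug_seq=0, drugname=drugname, role_cod="PS", prod_ai=prod_ai)
    scores = {e.product_id: _entry_match_score(probe, e) for e in dictionary}
    top = max(scores.values(), default=0)
    if top == 0:
        return ()
    return tuple(pid for pid, s in scores.items() if s == top)


def match_candidates(
    drug: DrugRecord, dictionary: Sequence[DrugDictionaryEntry]
) -> List[str]:
    """Product ids matching this record (role ignored), most specific only.

    When several products match, only those with the maximal matched
    component count are kept: a name spelling out a triple combination also
    contains the component set of the dual product nested inside it, and the
    longer match is the intended product, not an ambiguity. Results are
    memoized on the (drugname, prod_ai) strings, which repeat heavily in
    real data.
    """
    return list(_cached_candidates(drug.drugname, drug.prod_ai, tuple(dictionary)))


def match_target(
    drug: DrugRecord, dictionary: Sequence[DrugDictionaryEntry]
) -> Optional[str]:
    """Match one drug record to a product id; PS role required.

    Returns None for non-PS roles, no match, or an unresolvable ambiguity
    (two products tied at the same specificity — logged and excluded).
    """
    if drug.role_cod != "PS":
        return None
    cands = match_candidates(drug, dictionary)
    if len(cands) == 1:
        return cands[0]
    if len(cands) > 1:
        logger.warning(
            "ambiguous drug record %r / %r matches products %s; excluded",
            drug.drugname,
            drug.prod_ai,
            cands,
        )
    return None


@dataclass
class CaseMatch:
    product_id: Optional[str]
    matched_drug_seqs: List[int]
    ambiguous: bool = False


def match_case(bundle: CaseBundle, dictionary: Sequence[DrugDictionaryEntry]) -> CaseMatch:
    """Match a whole report: scan its PS drugs; distinct products -> ambiguous."""
    products: Dict[str, List[int]] = {}
    ambiguous_record = False
    for drug in bundle.drugs:
        if drug.role_cod != "PS":
            continue
        cands = match_candidates(drug, dictionary)
        if len(cands) > 1:
            ambiguous_record = True
            continue
        if len(cands) == 1:
            products.setdefault(cands[0], []).append(drug.drug_seq)
    if len(products) > 1 or (ambiguous_record and not products):
        if len(products) > 1:
            logger.warning(
                "case %s has PS matches to several products %s; excluded",
                bundle.primaryid,
                sorted(products),
            )
            return CaseMatch(None, [], ambiguous=True)
        return CaseMatch(None, [], ambiguous=ambiguous_record)
    if not products:
        return CaseMatch(None, [])
    (pid, seqs), = products.items()
    return CaseMatch(pid, seqs)


def in_search_window(
    case: CaseBundle,
    product: DrugDictionaryEntry,
    cutoff: Tuple[int, int] = SEARCH_CUTOFF_QUARTER,
) -> bool:
    """True iff the report's event quarter lies in [product start, cutoff]."""
    q = case.demographics.event_quarter
    if q is None:
        return False
    return product.search_start_quarter <= q <= cutoff


def most_severe(outcomes: Iterable[str]) -> Optional[str]:
    """Most severe outcome code under DE > LT > DS > CA > HO > RI > OT."""
    best: Optional[str] = None
    for code in outcomes:
        if code not in _SEVERITY_RANK:
            raise ValueError(f"unknown outcome code: {code!r}")
        if best is None or _SEVERITY_RANK[code] < _SEVERITY_RANK[best]:
            best = code
    return best


@dataclass
class ExtractResult:
    cases: List[CAECase]
    n_input: int
    n_without_cae: int
    unmapped_tally: Dict[str, int]


def extract_cae(
    matched: Iterable[Tuple[CaseBundle, str, List[int]]], meddra: MeddraMap
) -> ExtractResult:
    """Keep matched reports with >=1 cardiac PT; partition each report's PTs.

    ``matched`` yields (bundle, product_id, matched_drug_seqs). PTs absent
    from the dictionary go to the ``unmapped`` bucket (tallied), never to
    cardiac. PTs are counted once per report.
    """
    cases: List[CAECase] = []
    unmapped: Dict[str, int] = {}
    n_in = 0
    for bundle, product_id, seqs in matched:
        n_in += 1
        cae, other, unk = [], [], []
        for pt in bundle.unique_pts():
            soc = meddra.soc(pt)
            if soc is None:
                unk.append(pt)
                unmapped[pt] = unmapped.get(pt, 0) + 1
            elif soc == CARDIAC_SOC:
                cae.append(pt)
            else:
                other.append(pt)
        if not cae:
            continue
        cases.append(
            CAECase(
                bundle=bundle,
                product_id=product_id,
                cae_pts=cae,
                other_pts=other,
                unmapped_pts=unk,
                most_severe_outcome=most_severe(
                    [c for c in bundle.outcomes if c in _SEVERITY_RANK]
                ),
                matched_drug_seqs=list(seqs),
            )
        )
    return ExtractResult(
        cases=cases,
        n_input=n_in,
        n_without_cae=n_in - len(cases),
        unmapped_tally=unmapped,
    )


def soc_distribution(
    matched: Iterable[Tuple[CaseBundle, str]], meddra: MeddraMap
) -> pd.DataFrame:
    """Per-product event counts and percentages by SOC (PT once per report).

    Mirrors the SOC-level bar chart: each product's percentages sum to 100
    up to rounding. Unmapped PTs fall into an ``unmapped`` bucket.
    """
    rows = []
    for bundle, product_id in matched:
        for pt in bundle.unique_pts():
            soc = meddra.soc(pt) or "unmapped"
            rows.append((product_id, soc))
    if not rows:
        return pd.DataFrame(columns=["product_id", "soc", "n_events", "pct"])
    df = pd.DataFrame(rows, columns=["product_id", "soc"])
    counts = df.groupby(["product_id", "soc"], as_index=False).size()
    counts = counts.rename(columns={"size": "n_events"})
    totals = counts.groupby("product_id")["n_events"].transform("sum")
    counts["pct"] = 100.0 * counts["n_events"] / totals
    return counts.sort_values(
        ["product_id", "n_events", "soc"], ascending=[True, False, True]
    ).reset_index(drop=True)


def entry_for(product_id: str, dictionary: Sequence[DrugDictionaryEntry]) -> DrugDictionaryEntry:
    for e in dictionary:
        if e.product_id == product_id:
            return e
    raise KeyError(product_id)
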