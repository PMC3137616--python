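"""TRIM structural-class assignment from per-protein domain annotations.

TRIM (RBCC) proteins carry a RING, one or two B-boxes and a coiled-coil,
followed by C-terminal domains that define nine structural classes
(I: COS+FN3+B30.2 ... IX: ARF).  Classification keys on the C-terminal
domain content; completeness of the RBCC module is recorded as flags rather
than blocking the call, since loss of the RING or B-box is a recurrent
evolutionary event in fish.  Architectures absent from the canonical class
table are flagged as novel combinations; three named patterns (chromodomain
gain, RanBD/CypA gain, RING-TM-B30.2) are recognised specifically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

DOMAIN_VOCABULARY = frozenset(
    {
        "RING",
        "BBOX",
        "CC",
        "COS",
        "FN3",
        "B30.2",
        "PHD",
        "BROMO",
        "NHL",
        "FILAMIN",
        "ARF",
        "PYRIN",
        "TM",
        "MATH",
        "CHROMO",
        "RANBD",
        "CYPA",
        "other",
    }
)

#: tokens belonging to the tripartite motif itself (not class-determining)
RBCC_DOMAINS = frozenset({"RING", "BBOX", "CC"})
#: tokens that never determine a canonical class (insertions/decorations)
NEUTRAL_DOMAINS = frozenset({"TM", "PYRIN", "other"})


class DomainVocabularyError(ValueError):
    pass


@dataclass
class ArchitectureCall:
    protein_id: str
    architecture: str  # ordered comma-separated domain string
    trim_class: str  # I..IX, unclassified, non-TRIM
    flags: set = field(default_factory=set)
    like_partner: str | None = None


def _load_class_table() -> dict:
    table = {}
    text = (
        resources.files("trimevol").joinpath("data/trim_classes.tsv").read_text()
    )
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        cls = parts[0]
        cterm = parts[1] if len(parts) > 1 else ""
        key = frozenset(t for t in cterm.split(",") if t)
        table[key] = cls
    return table


CLASS_TABLE = _load_class_table()
CANONICAL_ARCHITECTURES = {
    ("RING", "BBOX", "CC") + tuple(sorted(k)): v for k, v in CLASS_TABLE.items()
}


def _validate_domains(domains):
    for d in domains:
        if d not in DOMAIN_VOCABULARY:
            raise DomainVocabularyError(f"unknown domain token {d!r}")


def classify_architecture(protein_id: str, domains) -> ArchitectureCall:
    """Classify one protein from its ordered domain token list.

    ``domains`` may be a list of tokens or of (token, start, end) tuples
    (sorted by start before use).  An empty list yields non-TRIM, as does a
    protein with neither RING nor B-box; such B30.2-only proteins are not
    counted as Class IV.
    """
    if domains and not isinstance(domains[0], str):
        domains = [d[0] for d in sorted(domains, key=lambda d: (d[1], d[2]))]
    domains = list(domains)
    _validate_domains(domains)
    architecture = ",".join(domains)
    if not domains:
        return ArchitectureCall(protein_id, "", "non-TRIM", set())
    present = set(domains)
    flags: set = set()
    if "RING" not in present and "BBOX" not in present:
        # no tripartite motif at all: not a TRIM protein
        if "B30.2" in present:
            flags.add("B30.2_only")
        return ArchitectureCall(protein_id, architecture, "non-TRIM", flags)
    for dom, flag in (("RING", "missing_RING"), ("BBOX", "missing_BBOX"), ("CC", "missing_CC")):
        if dom not in present:
            flags.add(flag)
    cterm = frozenset(present - RBCC_DOMAINS - NEUTRAL_DOMAINS)
    trim_class = CLASS_TABLE.get(cterm)
    if trim_class is None:
        trim_class = "unclassified"
        flags.add("novel_combination")
    else:
        # canonical C-terminal content with an unexpected insertion (e.g.
        # RING-TM-B30.2) is still a class candidate, but flagged as novel
        if present & NEUTRAL_DOMAINS - {"other"}:
            flags.add("novel_combination")
    return ArchitectureCall(protein_id, architecture, trim_class, flags)


def classify_table(domain_table: pd.DataFrame) -> list:
    """Classify every protein of a (protein_id, domain, start, end) table."""
    calls = []
    for pid, sub in domain_table.groupby("protein_id", sort=True):
        rows = sorted(
            zip(sub["domain"], sub["start"], sub["end"]), key=lambda r: (r[1], r[2])
        )
        calls.append(classify_architecture(pid, rows))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "architecture": [c.architecture for c in calls],
            "trim_class": [c.trim_class for c in calls],
            "flags": [",".join(sorted(c.flags)) for c in calls],
            "like_partner": [c.like_partner or "" for c in calls],
        }
    )


_NOVEL_PATTERNS = (
    (
        "chromodomain_gain",
        "C-terminal chromodomain in place of the ancestral B30.2 (ftr06-like)",
        lambda doms: bool(doms) and doms[-1] == "CHROMO",
    ),
    (
        "cypA_gain",
        "C-terminal RanBD/cyclophilin-A module in place of the B30.2 (ftr52-like)",
        lambda doms: len(doms) >= 2 and doms[-2:] == ["RANBD", "CYPA"],
    ),
    (
        "ring_tm_b30.2",
        "transmembrane segment replacing the B-boxes/coiled-coil (btr31-like)",
        lambda doms: doms == ["RING", "TM", "B30.2"],
    ),
)


def detect_novel_combinations(calls) -> pd.DataFrame:
    """Group non-canonical architectures and name the known gain patterns."""
    rows: dict = {}
    for call in calls:
        if "novel_combination" not in call.flags:
            continue
        doms = call.architecture.split(",") if call.architecture else []
        pattern = ""
        description = ""
        for name, desc, match in _NOVEL_PATTERNS:
            if match(doms):
                pattern, description = name, desc
                break
        entry = rows.setdefault(
            call.architecture,
            {"architecture": call.architecture, "pattern": pattern,
             "description": description, "proteins": []},
        )
        entry["proteins"].append(call.protein_id)
    out = pd.DataFrame(
        [
            {
                "architecture": e["architecture"],
                "pattern": e["pattern"],
                "description": e["description"],
                "proteins": ",".join(sorted(e["proteins"])),
                "n_proteins": len(e["proteins"]),
            }
            for e in rows.values()
        ],
        columns=["architecture", "pattern", "description", "proteins", "n_proteins"],
    )
    return out.sort_values("architecture").reset_index(drop=True) if len(out) else out


def call_like_variants(
    calls,
    identity: pd.DataFrame,
    threshold: float = 0.7,
):
    """Pair C-terminally truncated proteins with full-architecture relatives.

    A truncated protein (RBCC present but no class-determining C-terminal
    domain) is paired with its most sequence-similar full-architecture
    protein when pairwise identity >= ``threshold``; the pair mirrors the
    'same name + like suffix' co-orthologue convention.  Ties are broken by
    lexicographically smallest partner id and reported.  Returns
    (pairs, ties) where pairs is a list of (truncated_id, partner_id).
    """
    idm = identity
    vals = idm.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1] or not np.allclose(vals, vals.T, atol=1e-9):
        raise ValueError("identity matrix must be square and symmetric")
    if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
        raise ValueError("identities must lie in [0, 1]")
    by_id = {c.protein_id: c for c in calls}
    full = [
        c.protein_id
        for c in calls
        if c.trim_class not in ("non-TRIM",)
        and frozenset(c.architecture.split(",")) - RBCC_DOMAINS - NEUTRAL_DOMAINS
        and c.protein_id in idm.index
    ]
    pairs = []
    ties = []
    for call in calls:
        if call.trim_class == "non-TRIM" or call.protein_id not in idm.index:
            continue
        cterm = frozenset(call.architecture.split(",")) - RBCC_DOMAINS - NEUTRAL_DOMAINS
        if cterm:
            continue  # has a terminal domain: not truncated
        candidates = [f for f in full if f != call.protein_id]
        if not candidates:
            continue
        sims = idm.loc[call.protein_id, candidates].to_numpy(dtype=float)
        best = np.nanmax(sims)
        if not best >= threshold:
            continue
        best_ids = sorted(
            c for c, s in zip(candidates, sims) if abs(s - best) <= 1e-12
        )
        partner = best_ids[0]
        if len(best_ids) > 1:
            ties.append((call.protein_id, tuple(best_ids)))
        call.flags.add("like_variant")
        call.like_partner = partner
        pairs.append((call.protein_id, partner))
    return pairs, ties
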