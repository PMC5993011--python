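"""Packaged catalog of B. subtilis sigma factors.

Fifteen sigma factors grouped into two domains: the sigma-54 family
(SigL alone) and the sigma-70 family (SigA and the alternative and
sporulation factors).  Each entry carries the number of operons the
factor is annotated to regulate.  The catalog is read-only reference
data; it makes no percentage claims (the share of promoters attributed
to a factor depends on a denominator this table does not define).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .errors import CatalogIntegrityError

EXPECTED_FACTOR_COUNT = 15
# sum of the packaged per-factor operon counts, fixed at fixture-build time
EXPECTED_OPERON_TOTAL = 778

_VALID_DOMAINS = ("sigma54", "sigma70")


@dataclass(frozen=True)
class SigmaFactor:
    name: str
    domain: str  # 'sigma54' or 'sigma70'
    description: str
    operon_count: int

    def __post_init__(self):
        if self.domain not in _VALID_DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.operon_count < 0:
            raise ValueError("operon_count must be non-negative")


def load_catalog() -> tuple[SigmaFactor, ...]:
    """Load the packaged sigma-factor catalog.

    Integrity-checked on every load: exactly 15 uniquely named factors,
    exactly one sigma-54 member, and the fixed operon-count total.
    """
    text = resources.files("bacprom.data").joinpath("sigma_factors.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    try:
        factors = tuple(
            SigmaFactor(
                name=row["name"],
                domain=row["domain"],
                description=row["description"],
                operon_count=int(row["operons"]),
            )
            for row in rows
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise CatalogIntegrityError(f"packaged catalog is corrupted: {exc}") from exc

    names = [f.name for f in factors]
    if len(factors) != EXPECTED_FACTOR_COUNT:
        raise CatalogIntegrityError(
            f"expected {EXPECTED_FACTOR_COUNT} sigma factors, found {len(factors)}"
        )
    if len(set(names)) != len(names):
        raise CatalogIntegrityError("duplicate sigma factor names in catalog")
    sigma54 = [f for f in factors if f.domain == "sigma54"]
    if [f.name for f in sigma54] != ["SigL"]:
        raise CatalogIntegrityError("sigma54 domain must contain exactly SigL")
    total = sum(f.operon_count for f in factors)
    if total != EXPECTED_OPERON_TOTAL:
        raise CatalogIntegrityError(
            f"operon-count total {total} != packaged constant {EXPECTED_OPERON_TOTAL}"
        )
    return factors


def operon_summary(
    catalog: tuple[SigmaFactor, ...] | list[SigmaFactor],
) -> tuple[dict[str, int], int]:
    """Per-factor operon counts ordered by descending count, plus total.

    Ties keep catalog order (stable sort), so repeated calls give an
    identical ordering.
    """
    ordered = sorted(catalog, key=lambda f: -f.operon_count)
    counts = {f.name: f.operon_count for f in ordered}
    return counts, sum(counts.values())


def export_catalog_csv(path) -> None:
    """Write the catalog to ``path`` as CSV."""
    factors = load_catalog()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "domain", "description", "operon_count"])
        for f in factors:
            writer.writerow([f.name, f.domain, f.description, f.operon_count])
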