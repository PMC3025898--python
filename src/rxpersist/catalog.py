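"""Insulin product classification.

Every insulin product dispensed in the claims is classified along two axes:

* ``insulin_class`` — ``basal`` (long-acting background insulin: NPH, lente,
  glargine, detemir), ``mealtime`` (rapid/short-acting prandial insulin:
  lispro, aspart, glulisine, regular human) or ``mixture`` (fixed-ratio
  basal/mealtime premix).
* ``insulin_type`` — ``human`` (recombinant human-sequence insulin) or
  ``analog`` (modified recombinant insulin).

The classification ships as an editable CSV resource
(``data/insulin_products.csv``).  Administration form (pen vs vial/syringe)
is *not* a property of the product here; it travels on each pharmacy claim,
because the same brand is dispensed in both presentations.

Matching is exact on the normalized name (upper-cased, internal whitespace
collapsed); there is no fuzzy matching, so an unknown product raises
:class:`UnclassifiedProductError` and is never silently dropped — the cohort
builder counts such rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "INSULIN_CLASSES",
    "INSULIN_TYPES",
    "InsulinProductInfo",
    "UnclassifiedProductError",
    "InsulinCatalog",
    "default_catalog",
    "classify_product",
]

INSULIN_CLASSES = ("basal", "mealtime", "mixture")
INSULIN_TYPES = ("human", "analog")


def normalize_product_name(name: str) -> str:
    """Upper-case and collapse internal whitespace."""
    return " ".join(str(name).split()).upper()


@dataclass(frozen=True)
class InsulinProductInfo:
    """Classification of one insulin product."""

    product_name: str
    insulin_class: str
    insulin_type: str

    def __post_init__(self) -> None:
        if self.insulin_class not in INSULIN_CLASSES:
            raise ValueError(f"invalid insulin_class: {self.insulin_class!r}")
        if self.insulin_type not in INSULIN_TYPES:
            raise ValueError(f"invalid insulin_type: {self.insulin_type!r}")


class UnclassifiedProductError(KeyError):
    """Raised when a product name is absent from the catalog."""

    def __init__(self, product_name: str):
        super().__init__(product_name)
        self.product_name = product_name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unclassified product: {self.product_name!r}"


class InsulinCatalog:
    """Lookup table from product name to :class:`InsulinProductInfo`."""

    def __init__(self, entries: Iterable[InsulinProductInfo]):
        self._by_name: dict[str, InsulinProductInfo] = {}
        for info in entries:
            key = normalize_product_name(info.product_name)
            existing = self._by_name.get(key)
            if existing is not None and (
                existing.insulin_class != info.insulin_class
                or existing.insulin_type != info.insulin_type
            ):
                raise ValueError(f"conflicting catalog entries for {key!r}")
            self._by_name[key] = InsulinProductInfo(
                key, info.insulin_class, info.insulin_type
            )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "InsulinCatalog":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            entries = [
                InsulinProductInfo(
                    row["product_name"], row["insulin_class"], row["insulin_type"]
                )
                for row in reader
            ]
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["product_name", "insulin_class", "insulin_type"])
            for info in self:
                writer.writerow(
                    [info.product_name, info.insulin_class, info.insulin_type]
                )

    # -- queries ----------------------------------------------------------
    def classify(self, product_name: str) -> InsulinProductInfo:
        if not str(product_name).strip():
            raise ValueError("product name must be non-empty")
        key = normalize_product_name(product_name)
        try:
            return self._by_name[key]
        except KeyError:
            raise UnclassifiedProductError(product_name) from None

    def class_map(self) -> Mapping[str, str]:
        """Normalized name -> insulin_class, for vectorized joins."""
        return {k: v.insulin_class for k, v in self._by_name.items()}

    def type_map(self) -> Mapping[str, str]:
        return {k: v.insulin_type for k, v in self._by_name.items()}

    def products(self, insulin_class: str | None = None) -> list[str]:
        return [
            k
            for k, v in sorted(self._by_name.items())
            if insulin_class is None or v.insulin_class == insulin_class
        ]

    def __contains__(self, product_name: str) -> bool:
        return normalize_product_name(product_name) in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(sorted(self._by_name.values(), key=lambda i: i.product_name))


_DEFAULT: InsulinCatalog | None = None


def default_catalog() -> InsulinCatalog:
    """The catalog shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("rxpersist").joinpath("data/insulin_products.csv")
        with resources.as_file(ref) as path:
            _DEFAULT = InsulinCatalog.from_csv(path)
    return _DEFAULT


def classify_product(
    product_name: str, catalog: InsulinCatalog | None = None
) -> InsulinProductInfo:
    """Classify one product name against ``catalog`` (default: shipped catalog)."""
    return (catalog or default_catalog()).classify(product_name)
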