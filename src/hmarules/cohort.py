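"""Domain model for HMA-treated MDS cohorts.

A cohort couples gene-level somatic mutation calls (presence/absence over a
fixed myeloid gene panel, optionally with variant allele fractions) with the
clinical annotations the downstream analysis needs: IWG response category,
overall survival, IPSS-R risk category, and therapy arm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenePanel",
    "MutationProfile",
    "ResponseCategory",
    "IPSSRCategory",
    "Therapy",
    "ClinicalRecord",
    "Cohort",
    "CohortError",
]


class CohortError(ValueError):
    """Raised when cohort data violate the domain invariants."""


class GenePanel:
    """An ordered, duplicate-free list of uppercase gene symbols.

    The ordering is stable and defines the column order of every matrix
    derived from the panel.
    """

    def __init__(self, genes: Iterable[str]):
        normalized = [str(g).strip().upper() for g in genes]
        if not normalized:
            raise CohortError("gene panel must be non-empty")
        if any(not g for g in normalized):
            raise CohortError("gene panel contains an empty symbol")
        seen = set()
        for g in normalized:
            if g in seen:
                raise CohortError(f"duplicate gene symbol in panel: {g}")
            seen.add(g)
        self._genes: tuple[str, ...] = tuple(normalized)
        self._index = {g: i for i, g in enumerate(self._genes)}

    @property
    def genes(self) -> tuple[str, ...]:
        return self._genes

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, GenePanel) and other._genes == self._genes

    def __hash__(self) -> int:
        return hash(self._genes)

    def __repr__(self) -> str:
        return f"GenePanel({len(self)} genes)"

    def index(self, gene: str) -> int:
        g = str(gene).upper()
        if g not in self._index:
            raise CohortError(f"gene {g!r} is not in the panel")
        return self._index[g]


@dataclass(frozen=True)
class MutationProfile:
    """Per-patient gene-level mutation calls.

    ``mutations`` maps mutated gene symbol -> VAF (fraction in [0, 1]) or
    ``None`` when no VAF was recorded.  Wild-type genes are simply absent.
    """

    sample_id: str
    mutations: Mapping[str, Optional[float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sample_id:
            raise CohortError("sample_id must be non-empty")
        clean: dict[str, Optional[float]] = {}
        for gene, vaf in dict(self.mutations).items():
            g = str(gene).upper()
            if vaf is not None:
                vaf = float(vaf)
                if not (0.0 <= vaf <= 1.0):
                    raise CohortError(
                        f"sample {self.sample_id}: VAF {vaf} for {g} outside [0, 1]"
                    )
            clean[g] = vaf
        object.__setattr__(self, "mutations", clean)

    @property
    def mutated_genes(self) -> frozenset[str]:
        return frozenset(self.mutations)

    @property
    def mutation_count(self) -> int:
        return len(self.mutations)

    def has(self, gene: str) -> bool:
        return str(gene).upper() in self.mutations


class ResponseCategory(enum.Enum):
    """IWG response category.

    Responders are CR/PR/HI; nonresponders are SD/PD.  UNKNOWN is neither and
    is excluded from response-based analyses.
    """

    CR = "CR"
    PR = "PR"
    HI = "HI"
    SD = "SD"
    PD = "PD"
    UNKNOWN = "UNKNOWN"

    def responder(self) -> bool:
        return self in (ResponseCategory.CR, ResponseCategory.PR, ResponseCategory.HI)

    def nonresponder(self) -> bool:
        return self in (ResponseCategory.SD, ResponseCategory.PD)

    def evaluable(self) -> bool:
        return self is not ResponseCategory.UNKNOWN


class IPSSRCategory(enum.Enum):
    VERY_LOW = "VERY_LOW"
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"
    VERY_HIGH = "VERY_HIGH"
    UNKNOWN = "UNKNOWN"


class Therapy(enum.Enum):
    AZA = "AZA"
    DAC = "DAC"
    AZA_COMBO = "AZA_COMBO"
    DAC_COMBO = "DAC_COMBO"
    UNKNOWN = "UNKNOWN"


def _parse_enum(cls, token: str, field_name: str):
    t = str(token).strip().upper()
    try:
        return cls(t)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise CohortError(
            f"unknown {field_name} token {token!r}; allowed: {allowed}"
        ) from None


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical annotations for one patient.

    ``os_months``/``os_event`` are present together or absent together; a
    missing pair excludes the patient from survival analyses only.
    """

    sample_id: str
    response: ResponseCategory = ResponseCategory.UNKNOWN
    os_months: Optional[float] = None
    os_event: Optional[int] = None
    ipssr: IPSSRCategory = IPSSRCategory.UNKNOWN
    therapy: Therapy = Therapy.UNKNOWN

    def __post_init__(self):
        if not self.sample_id:
            raise CohortError("sample_id must be non-empty")
        if (self.os_months is None) != (self.os_event is None):
            raise CohortError(
                f"sample {self.sample_id}: os_months and os_event must be "
                "present together"
            )
        if self.os_months is not None:
            if self.os_months < 0:
                raise CohortError(
                    f"sample {self.sample_id}: negative os_months {self.os_months}"
                )
            if self.os_event not in (0, 1):
                raise CohortError(
                    f"sample {self.sample_id}: os_event must be 0 or 1"
                )

    @property
    def has_survival(self) -> bool:
        return self.os_months is not None

    @staticmethod
    def parse_response(token: str) -> ResponseCategory:
        return _parse_enum(ResponseCategory, token, "response")

    @staticmethod
    def parse_ipssr(token: str) -> IPSSRCategory:
        return _parse_enum(IPSSRCategory, token, "ipssr")

    @staticmethod
    def parse_therapy(token: str) -> Therapy:
        return _parse_enum(Therapy, token, "therapy")


class Cohort:
    """Aligned mutation profiles and clinical records over one gene panel.

    Profiles and clinical records are matched 1:1 on ``sample_id``; the panel
    fixes matrix column order.
    """

    def __init__(
        self,
        panel: GenePanel,
        profiles: Sequence[MutationProfile],
        clinical: Sequence[ClinicalRecord],
    ):
        ids = [p.sample_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate sample_ids among profiles")
        clin_ids = [c.sample_id for c in clinical]
        if len(set(clin_ids)) != len(clin_ids):
            raise CohortError("duplicate sample_ids among clinical records")
        if set(ids) != set(clin_ids):
            missing = set(ids) ^ set(clin_ids)
            raise CohortError(
                f"profiles and clinical records are not 1:1; unmatched ids: "
                f"{sorted(missing)[:5]}..."
            )
        for p in profiles:
            for g in p.mutations:
                if g not in panel:
                    raise CohortError(
                        f"sample {p.sample_id}: gene {g} not in panel"
                    )
        self.panel = panel
        self.profiles: tuple[MutationProfile, ...] = tuple(profiles)
        clin_by_id = {c.sample_id: c for c in clinical}
        self.clinical: tuple[ClinicalRecord, ...] = tuple(
            clin_by_id[i] for i in ids
        )

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def status_matrix(self) -> pd.DataFrame:
        """Binary patient x gene mutation matrix (0/1), panel column order."""
        mat = np.zeros((len(self.profiles), len(self.panel)), dtype=np.uint8)
        for i, p in enumerate(self.profiles):
            for g in p.mutations:
                mat[i, self.panel.index(g)] = 1
        return pd.DataFrame(mat, index=self.sample_ids, columns=list(self.panel))

    def mutation_counts(self) -> np.ndarray:
        return np.array([p.mutation_count for p in self.profiles], dtype=int)

    def responder_mask(self) -> np.ndarray:
        return np.array([c.response.responder() for c in self.clinical])

    def nonresponder_mask(self) -> np.ndarray:
        return np.array([c.response.nonresponder() for c in self.clinical])

    def evaluable_mask(self) -> np.ndarray:
        return np.array([c.response.evaluable() for c in self.clinical])

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            self.panel,
            [p for p, m in zip(self.profiles, mask) if m],
            [c for c, m in zip(self.clinical, mask) if m],
        )
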