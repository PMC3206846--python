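"""In-silico restriction digestion: predicted 5'-terminal fragment lengths.

For each phylotype representative and enzyme, the predicted terminal
restriction fragment (T-RF) is the length of the labeled 5' fragment left
by the earliest recognition-site occurrence:

    trf = (site_start - 1) + cut_offset + primer_offset

where ``cut_offset`` is the number of recognition-site bases retained on
the labeled fragment (HaeIII GG^CC -> 2, MspI C^CGG -> 1, RsaI GT^AC -> 2,
standard REBASE cut positions). Degenerate IUPAC codes in the recognition
sequence expand; degenerate codes in the *sequence* (e.g. N) never match —
a conservative rule that avoids phantom sites. All three built-in sites are
palindromic, so only the sense strand is searched; a non-palindromic user
enzyme triggers a dual-strand search taking the shorter labeled fragment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import SequenceRecord, write_json

__all__ = [
    "RestrictionEnzyme",
    "ReferenceTRFDatabase",
    "BUILTIN_ENZYMES",
    "find_first_site",
    "predict_trf",
    "in_window",
    "build_reference_db",
]

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition site")

    @property
    def is_palindromic(self) -> bool:
        return _revcomp(self.recognition) == self.recognition

    def pattern(self) -> re.Pattern[str]:
        # degenerate recognition bases expand to character classes; the
        # scanned sequence must contain plain A/C/G/T at the site (N in the
        # sequence never matches)
        return re.compile(
            "".join(f"[{IUPAC_EXPAND[b]}]" for b in self.recognition)
        )


BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "HaeIII": RestrictionEnzyme("HaeIII", "GGCC", 2),
    "MspI": RestrictionEnzyme("MspI", "CCGG", 1),
    "RsaI": RestrictionEnzyme("RsaI", "GTAC", 2),
}


def find_first_site(seq: SequenceRecord, enzyme: RestrictionEnzyme) -> int | None:
    """1-based start of the earliest recognition-site occurrence, or None."""
    m = enzyme.pattern().search(seq.sequence)
    return m.start() + 1 if m else None


def predict_trf(
    seq: SequenceRecord,
    enzyme: RestrictionEnzyme,
    primer_offset: int = 0,
) -> int | None:
    """Predicted labeled-fragment length in bp, or None when no site exists."""
    pos = find_first_site(seq, enzyme)
    if enzyme.is_palindromic:
        return None if pos is None else (pos - 1) + enzyme.cut_offset + primer_offset
    # non-palindromic enzyme: also search the reverse-complement site on the
    # sense strand; the labeled fragment ends at the cut on whichever strand
    # cuts first
    rc = RestrictionEnzyme(
        enzyme.name + "_rc",
        _revcomp(enzyme.recognition),
        len(enzyme.recognition) - enzyme.cut_offset,
    )
    pos_rc = find_first_site(seq, rc)
    lengths = [
        (p - 1) + e.cut_offset
        for p, e in ((pos, enzyme), (pos_rc, rc))
        if p is not None
    ]
    return min(lengths) + primer_offset if lengths else None


def in_window(trf: float | None, window: tuple[float, float] = (100.0, 500.0)) -> bool:
    """True iff the prediction lies in the accurate sizing range, inclusive."""
    if trf is None:
        return False
    return window[0] <= trf <= window[1]


@dataclass
class ReferenceTRFDatabase:
    """Per-phylotype, per-enzyme predicted T-RFs with detection-window flags."""

    entries: dict[str, dict[str, int | None]]
    detection_window: tuple[float, float] = (100.0, 500.0)
    primer_offset: int = 0
    enzymes: list[str] = field(default_factory=list)

    def in_window(self, otu_id: str, enzyme: str) -> bool:
        return in_window(self.entries[otu_id][enzyme], self.detection_window)

    def summary(self) -> dict:
        """Per-enzyme and combined counts of phylotypes detectable in-window."""
        n = len(self.entries)
        per_enzyme = {}
        for enz in self.enzymes:
            k = sum(1 for o in self.entries if self.in_window(o, enz))
            per_enzyme[enz] = {"n_in_window": k, "fraction": k / n if n else 0.0}
        any_k = sum(
            1 for o in self.entries if any(self.in_window(o, e) for e in self.enzymes)
        )
        return {
            "n_otus": n,
            "per_enzyme": per_enzyme,
            "n_any_enzyme": any_k,
            "fraction_any_enzyme": any_k / n if n else 0.0,
            "n_undetectable": n - any_k,
        }

    def to_json(self, path) -> None:
        payload = {
            "params": {
                "detection_window": list(self.detection_window),
                "primer_offset": self.primer_offset,
                "enzymes": self.enzymes,
            },
            "entries": {
                o: {
                    e: {
                        "trf": self.entries[o][e],
                        "in_window": self.in_window(o, e),
                    }
                    for e in self.enzymes
                }
                for o in self.entries
            },
        }
        write_json(payload, path)

    @classmethod
    def from_json(cls, path) -> "ReferenceTRFDatabase":
        import json

        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        params = payload["params"]
        entries = {
            o: {e: v["trf"] for e, v in enz.items()}
            for o, enz in payload["entries"].items()
        }
        return cls(
            entries=entries,
            detection_window=tuple(params["detection_window"]),
            primer_offset=params["primer_offset"],
            enzymes=params["enzymes"],
        )


def build_reference_db(
    reps: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    enzymes: Iterable[RestrictionEnzyme | str] = ("HaeIII", "MspI", "RsaI"),
    window: tuple[float, float] = (100.0, 500.0),
    primer_offset: int = 0,
) -> ReferenceTRFDatabase:
    """Predict the full phylotype x enzyme T-RF grid."""
    if not isinstance(reps, Mapping):
        ids = [r.id for r in reps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate OTU ids among representatives")
        reps = {r.id: r for r in reps}
    enz_objs = [
        BUILTIN_ENZYMES[e] if isinstance(e, str) else e for e in enzymes
    ]
    if not reps or not enz_objs:
        raise ValueError("need at least one representative and one enzyme")
    entries = {
        otu: {
            e.name: predict_trf(rec, e, primer_offset=primer_offset)
            for e in enz_objs
        }
        for otu, rec in reps.items()
    }
    return ReferenceTRFDatabase(
        entries=entries,
        detection_window=window,
        primer_offset=primer_offset,
        enzymes=[e.name for e in enz_objs],
    )
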