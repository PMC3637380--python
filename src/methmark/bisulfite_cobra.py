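"""In-silico bisulfite conversion, tagged-primer PCR, and COBRA digestion.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected.  On the top strand this
means: every C outside a CpG becomes T; a CpG C becomes T when
unmethylated and stays C when methylated.  Conversion is modelled at 100%
efficiency on the top strand.

Combined Bisulfite Restriction Analysis (COBRA) exploits the fact that a
restriction site containing CG survives conversion only when its CpG was
methylated.  HpyCH4IV (ACGT) cuts A^CGT: a genomic ACGT stays ACGT when
the CpG is methylated (cut) and becomes ATGT when not (uncut).  TaqI
(TCGA) cuts T^CGA and additionally gains sites from methylated CCGA,
which converts to TCGA.  Digesting the bisulfite-PCR product and counting
cut vs uncut molecules therefore reads out the methylation fraction at
the assayed CpG — the in-silico analogue of scoring gel bands against
0 / 50 / 100 % methylated control DNA.

Primers are written against the *converted* top strand and carry 5'
tags in lower case (a forward tag and a reverse T7-promoter tag for
downstream in-vitro transcription); only the upper-case genomic part
anneals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ValidationError

__all__ = [
    "MethylTemplate",
    "TaggedPrimer",
    "EnzymeSite",
    "Amplicon",
    "DigestResult",
    "ENZYMES",
    "bisulfite_convert",
    "in_silico_pcr",
    "digest",
    "cobra_call",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MethylTemplate:
    """A genomic template with a population of per-molecule CpG states.

    ``cpg_positions`` are 1-based positions of the C of each CpG;
    ``methyl_states`` is a molecules x CpGs boolean array (True =
    methylated).
    """

    sequence: str
    cpg_positions: tuple[int, ...]
    methyl_states: np.ndarray

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValidationError(f"non-ACGT characters in template: {sorted(bad)}")
        self.sequence = self.sequence.upper()
        for p in self.cpg_positions:
            if not 1 <= p < len(self.sequence):
                raise ValidationError(f"CpG position {p} outside template")
            if self.sequence[p - 1 : p + 1] != "CG":
                raise ValidationError(
                    f"position {p} is not the C of a CpG "
                    f"(found {self.sequence[p - 1:p + 1]!r})"
                )
        self.methyl_states = np.asarray(self.methyl_states, dtype=bool)
        if self.methyl_states.ndim != 2 or self.methyl_states.shape[1] != len(
            self.cpg_positions
        ):
            raise ValidationError(
                "methyl_states must be (n_molecules, n_cpgs) boolean"
            )

    @property
    def n_molecules(self) -> int:
        return self.methyl_states.shape[0]


@dataclass
class TaggedPrimer:
    """A PCR primer with a lower-case 5' tag and upper-case genomic part."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        i = 0
        while i < len(seq) and seq[i].islower():
            i += 1
        if any(c.islower() for c in seq[i:]):
            raise ValidationError(
                f"primer {self.name}: tag (lower case) must be a 5' prefix"
            )
        if len(seq) - i < 15:
            raise ValidationError(
                f"primer {self.name}: genomic part shorter than 15 nt"
            )
        self._tag_len = i

    @property
    def tag(self) -> str:
        return self.sequence[: self._tag_len]

    @property
    def genomic(self) -> str:
        return self.sequence[self._tag_len :]


@dataclass(frozen=True)
class EnzymeSite:
    """A restriction enzyme recognising a CG-containing site on the product.

    ``cut_offset`` is the top-strand cut position within the recognition
    sequence (1 for A^CGT and T^CGA).  ``cg_offset`` locates the CG core
    within the site, used to align the site with an assayed CpG.
    """

    name: str
    recognition: str
    cut_offset: int = 1
    note: str = ""

    def __post_init__(self) -> None:
        if "CG" not in self.recognition:
            raise ValidationError(
                f"{self.name}: recognition {self.recognition!r} lacks the CG core"
            )

    @property
    def cg_offset(self) -> int:
        return self.recognition.index("CG")


ENZYMES: dict[str, EnzymeSite] = {
    "HpyCH4IV": EnzymeSite(
        "HpyCH4IV", "ACGT", 1, "site survives conversion only at a methylated CpG"
    ),
    "TaqI": EnzymeSite(
        "TaqI", "TCGA", 1, "genomic CCGA converts to TCGA when the CpG is methylated"
    ),
}


def bisulfite_convert(template: MethylTemplate, molecule: int) -> str:
    """Top-strand bisulfite conversion of one molecule, 100% efficiency.

    Cs outside CpGs always read T; a CpG C reads C when methylated in
    this molecule and T otherwise.  Sequence length is unchanged and
    A/G/T positions are fixed points.
    """
    seq = list(template.sequence)
    methylated = {
        p
        for p, state in zip(template.cpg_positions, template.methyl_states[molecule])
        if state
    }
    for i, base in enumerate(seq):
        if base == "C" and (i + 1) not in methylated:
            seq[i] = "T"
    return "".join(seq)


@dataclass
class Amplicon:
    """One molecule's PCR product in converted coordinates.

    ``template_start``/``template_end`` are the 0-based half-open bounds
    of the genomic insert on the template; the product sequence is
    ``fwd_tag + insert + revcomp(rev_tag)`` with tags in lower case.
    """

    sequence: str
    molecule: int
    template_start: int
    template_end: int
    tag5_len: int
    tag3_len: int
    covered_cpgs: tuple[int, ...]  # template 1-based CpG positions inside the insert

    def product_index(self, template_pos: int) -> int:
        """Map a 1-based template position into the product string."""
        if not self.template_start < template_pos <= self.template_end:
            raise ValidationError(
                f"template position {template_pos} outside amplicon "
                f"({self.template_start + 1}..{self.template_end})"
            )
        return self.tag5_len + (template_pos - 1 - self.template_start)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def in_silico_pcr(
    template: MethylTemplate,
    forward: TaggedPrimer,
    reverse: TaggedPrimer,
    molecules: Iterable[int] | None = None,
) -> list[Amplicon]:
    """Amplify each converted molecule with a tagged primer pair.

    The forward genomic part must match the converted top strand exactly;
    the reverse genomic part's reverse complement must match downstream
    of it.  Molecules without both matches yield no product; more than
    one candidate product is an assay-design error.
    """
    if molecules is None:
        molecules = range(template.n_molecules)
    rev_site = reverse_complement(reverse.genomic.upper())
    fwd_site = forward.genomic.upper()
    amplicons: list[Amplicon] = []
    for m in molecules:
        converted = bisulfite_convert(template, m)
        fwd_hits = _find_all(converted, fwd_site)
        rev_hits = _find_all(converted, rev_site)
        products = [
            (s, t + len(rev_site))
            for s in fwd_hits
            for t in rev_hits
            if t >= s + len(fwd_site)
        ]
        if not products:
            continue
        if len(products) > 1:
            loci = ", ".join(f"{s + 1}..{e}" for s, e in products)
            raise ValidationError(
                f"ambiguous amplification (molecule {m}): candidate products at {loci}"
            )
        start, end = products[0]
        insert = converted[start:end]
        covered = tuple(
            p for p in template.cpg_positions if start < p <= end
        )
        amplicons.append(
            Amplicon(
                sequence=forward.tag + insert + reverse_complement(reverse.tag),
                molecule=m,
                template_start=start,
                template_end=end,
                tag5_len=len(forward.tag),
                tag3_len=len(reverse.tag),
                covered_cpgs=covered,
            )
        )
    return amplicons


@dataclass
class DigestResult:
    """Digestion of an amplicon population with one enzyme.

    ``fragments`` lists each molecule's ordered fragment lengths (always
    summing to that molecule's product length).  ``site_cut_fraction``
    gives, per covered CpG (template 1-based position), the fraction of
    molecules in which the enzyme's site was present across that CpG.
    ``gel`` is the fragment-length histogram over all molecules — the
    in-silico band pattern.
    """

    enzyme: EnzymeSite
    fragments: list[tuple[int, ...]]
    site_cut_fraction: dict[int, float]
    gel: Counter
    n_molecules: int


def digest(amplicons: Sequence[Amplicon], enzyme: EnzymeSite) -> DigestResult:
    """Cut every recognition-site occurrence in each product.

    Matching is case-insensitive so constant sites falling in the primer
    tags are cut too (as they would be in a real double-stranded
    product).
    """
    fragments: list[tuple[int, ...]] = []
    gel: Counter = Counter()
    cut_counts: Counter = Counter()
    covered_counts: Counter = Counter()
    recog = enzyme.recognition.upper()
    for amp in amplicons:
        seq = amp.sequence.upper()
        cut_points = sorted(h + enzyme.cut_offset for h in _find_all(seq, recog))
        bounds = [0] + cut_points + [len(seq)]
        frags = tuple(b - a for a, b in zip(bounds, bounds[1:]) if b > a)
        fragments.append(frags)
        gel.update(frags)
        for p in amp.covered_cpgs:
            covered_counts[p] += 1
            site_start = amp.product_index(p) - enzyme.cg_offset
            if site_start >= 0 and seq[site_start : site_start + len(recog)] == recog:
                cut_counts[p] += 1
    site_cut_fraction = {
        p: cut_counts[p] / covered_counts[p] for p in sorted(covered_counts)
    }
    return DigestResult(
        enzyme=enzyme,
        fragments=fragments,
        site_cut_fraction=site_cut_fraction,
        gel=gel,
        n_molecules=len(amplicons),
    )


def cobra_call(
    result: DigestResult, site: int, cut_fraction_threshold: float = 0.5
) -> str:
    """Binary methylation call at one assayed CpG site.

    ``hypermethylated`` iff the cut fraction at the site exceeds the
    threshold (default 0.5, the midpoint between the 0% and 100%
    methylated controls).
    """
    if site not in result.site_cut_fraction:
        raise ValidationError(
            f"site {site} is not covered by the digested amplicons"
        )
    return (
        "hypermethylated"
        if result.site_cut_fraction[site] > cut_fraction_threshold
        else "unmethylated"
    )


def gel_table(result: DigestResult) -> str:
    """Text rendering of the fragment-length histogram (the 'gel')."""
    lines = ["length_bp\tmolecules"]
    for length in sorted(result.gel, reverse=True):
        lines.append(f"{length}\t{result.gel[length]}")
    return "\n".join(lines)
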