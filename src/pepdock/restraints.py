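"""Contact restraints between receptor and peptide side chains.

A contact restraint names one receptor residue and one peptide residue (or
all peptide residues, the *ambiguous* mode) and penalises their SC-SC
distance ``d`` with a flat-bottom linear term::

    E(d) = 0            if d <= d0
    E(d) = s * (d - d0) if d >  d0

``d0`` (default 5.0 Å) is the largest distance treated as "in contact";
``s`` (default 1.0 energy/Å) is the slope of the penalty.  With the default
parameters the restraint is soft: it pulls a stray peptide toward the
binding site without freezing its internal flexibility once there.

The text grammar is one restraint per line (semicolons also accepted as
separators)::

    <residue1>:<chain> <residue2>:PEP [<d0> [<s>]]

e.g. ``1060:C 6:PEP 5.0 1.0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pepdock.cg_model import CGComplex

DEFAULT_D0 = 5.0       # Å
DEFAULT_WEIGHT = 1.0   # energy per Å
NATIVE_CONTACT_CUTOFF = 5.0  # Å, SC-SC distance strictly below => native contact
AMBIGUOUS = "ALL"


class RestraintError(ValueError):
    """Raised for malformed restraint input."""


@dataclass(frozen=True)
class ContactRestraint:
    """A single receptor-peptide contact restraint.

    ``peptide_residue`` is either a residue number within the peptide or the
    sentinel ``"ALL"``, meaning the restraint is satisfied by proximity to
    *any* peptide residue (minimum-distance rule).
    """

    receptor_residue: tuple[int, str]
    peptide_residue: int | str
    d0: float = DEFAULT_D0
    s: float = DEFAULT_WEIGHT

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise RestraintError(f"cutoff d0 must be positive, got {self.d0}")
        if self.s < 0:
            raise RestraintError(f"restraint weight must be non-negative, got {self.s}")
        if isinstance(self.peptide_residue, str) and self.peptide_residue != AMBIGUOUS:
            raise RestraintError(
                f"peptide residue must be a number or {AMBIGUOUS!r}, got {self.peptide_residue!r}")

    @property
    def is_ambiguous(self) -> bool:
        return self.peptide_residue == AMBIGUOUS

    def to_line(self) -> str:
        """Canonical four-token text form."""
        num, chain = self.receptor_residue
        return f"{num}:{chain} {self.peptide_residue}:PEP {self.d0:g} {self.s:g}"


@dataclass
class RestraintSet:
    restraints: list[ContactRestraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.restraints:
            key = (r.receptor_residue, r.peptide_residue)
            if key in seen:
                raise RestraintError(f"duplicate restraint on pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __bool__(self) -> bool:
        return bool(self.restraints)


def _parse_residue_token(token: str, what: str) -> tuple[str, str]:
    if ":" not in token:
        raise RestraintError(f"{what} token {token!r} must look like <number>:<chain>")
    num, chain = token.split(":", 1)
    if not chain:
        raise RestraintError(f"{what} token {token!r} has an empty chain id")
    return num, chain


def parse_restraint_line(line: str) -> ContactRestraint:
    """Parse one restraint line.

    Two, three, or four space-separated tokens; omitted cutoff/weight fall
    back to the defaults (5.0 Å, 1.0).
    """
    tokens = line.split()
    if len(tokens) < 2 or len(tokens) > 4:
        raise RestraintError(f"restraint line {line!r} must have 2-4 tokens")

    rec_num_s, rec_chain = _parse_residue_token(tokens[0], "receptor")
    pep_num_s, pep_chain = _parse_residue_token(tokens[1], "peptide")
    if pep_chain != "PEP":
        raise RestraintError(
            f"second residue of {line!r} must be on the peptide (suffix ':PEP')")
    try:
        rec_num = int(rec_num_s)
    except ValueError:
        raise RestraintError(f"receptor residue number {rec_num_s!r} is not an integer") from None
    if pep_num_s.upper() == AMBIGUOUS:
        pep_res: int | str = AMBIGUOUS
    else:
        try:
            pep_res = int(pep_num_s)
        except ValueError:
            raise RestraintError(f"peptide residue number {pep_num_s!r} is not an integer") from None

    d0, s = DEFAULT_D0, DEFAULT_WEIGHT
    try:
        if len(tokens) >= 3:
            d0 = float(tokens[2])
        if len(tokens) == 4:
            s = float(tokens[3])
    except ValueError:
        raise RestraintError(f"non-numeric cutoff/weight in {line!r}") from None
    return ContactRestraint(receptor_residue=(rec_num, rec_chain),
                            peptide_residue=pep_res, d0=d0, s=s)


def parse_restraint_block(text: str) -> RestraintSet:
    """Parse multi-restraint text; newlines and semicolons both separate."""
    restraints = []
    for segment in text.replace(";", "\n").splitlines():
        segment = segment.strip()
        if not segment:
            continue
        try:
            restraints.append(parse_restraint_line(segment))
        except RestraintError as err:
            raise RestraintError(f"bad restraint segment {segment!r}: {err}") from None
    return RestraintSet(restraints)


def restraint_energy(d: float, restraint: ContactRestraint) -> float:
    """Flat-bottom linear penalty: 0 for d <= d0, s*(d - d0) beyond."""
    if d < 0:
        raise RestraintError(f"distance must be non-negative, got {d}")
    if d <= restraint.d0:
        return 0.0
    return restraint.s * (d - restraint.d0)


def restraint_distance(cplx: CGComplex, restraint: ContactRestraint) -> float:
    """SC-SC distance for a restraint; minimum over the peptide if ambiguous."""
    rec = cplx.find_receptor_residue(*restraint.receptor_residue)
    if restraint.is_ambiguous:
        sc = cplx.peptide_sc()
        return float(np.min(np.linalg.norm(sc - rec.sc, axis=1)))
    pep = cplx.find_peptide_residue(restraint.peptide_residue)
    return float(np.linalg.norm(rec.sc - pep.sc))


def total_restraint_energy(cplx: CGComplex, restraints: RestraintSet) -> float:
    """Sum of the individual restraint penalties; 0 for an empty set."""
    return sum(restraint_energy(restraint_distance(cplx, r), r) for r in restraints)


def make_ambiguous_restraints(receptor_residue: tuple[int, str],
                              peptide_length: int,
                              s: float = DEFAULT_WEIGHT) -> RestraintSet:
    """Restrain one receptor residue to the whole peptide.

    Used when binding-site information names only a receptor residue.  The
    cutoff is ``peptide_length + 12`` Å, wide enough that any pose with the
    peptide draped over that residue satisfies it.
    """
    if peptide_length < 3:
        raise RestraintError("peptide length must be at least 3")
    return RestraintSet([ContactRestraint(
        receptor_residue=receptor_residue, peptide_residue=AMBIGUOUS,
        d0=float(peptide_length + 12), s=s)])


def extract_native_contacts(reference: CGComplex
                            ) -> list[tuple[tuple[int, str], int, float]]:
    """All receptor-peptide residue pairs with SC-SC distance < 5 Å.

    Returns ``(receptor (number, chain), peptide number, distance)`` triples
    sorted by distance ascending.
    """
    if not reference.peptide:
        raise RestraintError("reference complex has no peptide chain")
    contacts = []
    pep_sc = reference.peptide_sc()
    pep_nums = [r.residue_number for r in reference.peptide]
    for rec in reference.receptor_residues():
        dists = np.linalg.norm(pep_sc - rec.sc, axis=1)
        for num, d in zip(pep_nums, dists):
            if d < NATIVE_CONTACT_CUTOFF:
                contacts.append(((rec.residue_number, rec.chain_id), num, float(d)))
    contacts.sort(key=lambda c: c[2])
    return contacts


def pick_random_native_contact(contacts: list[tuple[tuple[int, str], int, float]],
                               rng_seed: int) -> ContactRestraint:
    """Uniformly choose one native contact and turn it into a default restraint."""
    if not contacts:
        raise RestraintError("contact list is empty")
    rng = np.random.default_rng(rng_seed)
    rec, pep, _dist = contacts[int(rng.integers(len(contacts)))]
    return ContactRestraint(receptor_residue=rec, peptide_residue=pep,
                            d0=DEFAULT_D0, s=DEFAULT_WEIGHT)
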