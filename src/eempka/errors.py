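"""Exception hierarchy.

Every failure mode has a dedicated class so callers (and the CLI exit-code
mapping) can distinguish parse problems, parameter problems and numerical
problems without string matching.
"""


class EempkaError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(EempkaError):
    """Non-finite coordinates or otherwise unusable geometry."""


class SingularGeometryError(EempkaError):
    """Two atoms coincide, making 1/R terms undefined."""


class MissingParameterError(EempkaError):
    """No (element, bond-order) entry in the parameter set for some atom."""

    def __init__(self, atom_index, element, bond_order, set_name):
        self.atom_index = atom_index
        self.element = element
        self.bond_order = bond_order
        self.set_name = set_name
        super().__init__(
            f"no EEM parameters for atom {atom_index} ({element}, "
            f"max bond order {bond_order}) in parameter set '{set_name}'"
        )


class SingularSystemError(EempkaError):
    """The EEM matrix is numerically singular."""


class ParseError(EempkaError):
    """Malformed SDF/MOL or delimited-table input."""


class SchemaError(EempkaError):
    """Parameter-set or table document violates its schema."""


class NoSiteError(EempkaError):
    """No dissociation site matches the requested pattern."""


class AmbiguousSiteError(EempkaError):
    """More than one candidate dissociation site."""

    def __init__(self, sites):
        self.sites = sites
        super().__init__(
            f"{len(sites)} candidate dissociation sites found: {sites}; "
            "pass an explicit site to disambiguate"
        )


class ConsistencyError(EempkaError):
    """Neutral/dissociated pair do not correspond atom-for-atom."""


class CollinearityError(EempkaError):
    """Rank-deficient (or zero-variance) design matrix."""


class JoinError(EempkaError):
    """Molecule ids do not align between descriptor and pKa tables."""


class DescriptorError(EempkaError):
    """A record lacks a descriptor the model requires."""


class DegenerateFoldError(EempkaError):
    """A cross-validation fold is too small to evaluate."""


class DegenerateLeverageError(EempkaError):
    """An observation with leverage 1 (exactly determining point)."""
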