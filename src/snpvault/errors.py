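"""Exception hierarchy for snpvault."""


class SnpVaultError(Exception):
    """Base class for all snpvault errors."""


class InvalidCodeError(SnpVaultError):
    """A genotype code outside {0, 1, 2, 3} was supplied."""


class AlleleMismatchError(SnpVaultError):
    """An observed allele does not belong to the SNP's allele coding."""


class DomainError(SnpVaultError):
    """A numeric argument lies outside its valid domain."""


class StoreError(SnpVaultError):
    """Generic datastore failure (schema mismatch, unwritable path...)."""


class UnknownEntityError(StoreError):
    """A named panel / selection / set / sample does not exist."""


class DuplicateEntityError(StoreError):
    """An entity with that name already exists."""


class DependentEntityError(StoreError):
    """Deletion refused because dependent entities exist (no cascade)."""

    def __init__(self, message: str, dependents: list[str]):
        super().__init__(message)
        self.dependents = dependents


class MapMismatchError(SnpVaultError):
    """A map file does not match the stored panel definition."""


class PedFormatError(SnpVaultError):
    """A ped/map/selection-list file is malformed."""


class EmptySelectionError(SnpVaultError):
    """An operation would produce (or export) an empty sample or SNP selection."""
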