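"""Exception hierarchy shared across the package."""


class StrokeDTIError(Exception):
    """Base class for all package errors."""


class OntologyFormatError(StrokeDTIError):
    """Ontology file malformed: duplicate ids/acronyms or unparseable records."""


class OntologyStructureError(StrokeDTIError):
    """Ontology parent links do not form a single tree rooted at 'root'."""


class RegionLookupError(StrokeDTIError, KeyError):
    """Unknown region id or acronym."""


class GridError(StrokeDTIError):
    """Volume shapes or affines are incompatible."""


class EmptyRegionError(StrokeDTIError):
    """Operation requires a nonempty region/mask but got an empty one."""


class ParameterError(StrokeDTIError, ValueError):
    """Invalid analysis parameter (e.g. k > n for clustering)."""


class IncompleteSeriesError(StrokeDTIError):
    """A required timepoint is missing from a longitudinal series."""


class DesignError(StrokeDTIError):
    """Invalid study design (group missing, n < 1, layout does not fit)."""
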