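"""Exception hierarchy for planmatch."""


class PlanmatchError(Exception):
    """Base class for all planmatch errors."""


class FormatError(PlanmatchError):
    """A file is not the expected DICOM-RT object or is structurally invalid."""


class CaseRejectedError(PlanmatchError):
    """A case directory cannot be turned into a database entry.

    Carries a human-readable reason (missing target, ambiguous files, ...).
    """


class IntegrityError(PlanmatchError):
    """A database archive is corrupted or has an incompatible schema version."""


class EmptyCloudError(PlanmatchError):
    """An operation that requires a nonempty point cloud received an empty one."""
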