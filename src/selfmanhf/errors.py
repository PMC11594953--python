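"""Exception types shared across the package."""

from __future__ import annotations


class ValidationError(ValueError):
    """An input violates a documented precondition (range, shape, missingness)."""


class SchemaError(ValidationError):
    """A cohort file violates the CSV schema.

    Carries the full list of problems so a malformed file is reported in one
    pass rather than one error at a time.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        summary = f"{len(self.problems)} schema problem(s):\n" + "\n".join(
            f"  - {p}" for p in self.problems
        )
        super().__init__(summary)
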