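"""Exception hierarchy."""


class ExplorersOwlsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExplorersOwlsError, ValueError):
    """Invalid board, reward, search or study configuration."""


class PhaseError(ExplorersOwlsError):
    """Operation called in the wrong game phase."""


class IllegalMoveError(ExplorersOwlsError):
    """A move that violates the rules; `rule` names the violated rule."""

    def __init__(self, message: str, rule: str = "unknown"):
        super().__init__(message)
        self.rule = rule


class SearchError(ExplorersOwlsError):
    """MCTS invoked on an unsearchable state (terminal, or no legal moves)."""


class PolicyError(ExplorersOwlsError):
    """A scripted policy was asked to act with no legal action available."""


class AggregationError(ExplorersOwlsError):
    """Summary statistics requested over an empty condition."""
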