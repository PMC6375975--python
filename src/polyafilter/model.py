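"""Model/Results façade over the functional API.

``PolyaFilter`` wraps a :class:`~polyafilter.network.WeightedNetwork` and
exposes testing, backbone extraction and calibration; ``fit`` returns a
``PolyaFilterResults`` object carrying the maximum-likelihood estimate of the
reinforcement parameter, the likelihood profile, and convenience methods to
extract backbones at the fitted value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import calibration, filtering, salience
from .network import WeightedNetwork, read_edgelist

__all__ = ["PolyaFilter", "PolyaFilterResults"]


class PolyaFilter:
    """Pólya urn filter for one weighted network.

    Parameters
    ----------
    network : WeightedNetwork
        The network whose links are to be tested against the Beta-Binomial
        null of self-reinforcing weight allocation.
    """

    def __init__(self, network: WeightedNetwork):
        self.network = network

    @classmethod
    def from_edgelist(cls, path, directed: bool = False) -> "PolyaFilter":
        return cls(read_edgelist(path, directed=directed))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        directed: bool = False,
        source: str = "source",
        target: str = "target",
        weight: str = "weight",
    ) -> "PolyaFilter":
        triples = zip(frame[source], frame[target], frame[weight])
        return cls(WeightedNetwork.from_links(triples, directed=directed))

    def pvalues(self, a: float, mode: str = "auto") -> filtering.TestTable:
        """Two-viewpoint p-value table at reinforcement parameter ``a``."""
        return filtering.link_pvalues(self.network, a, mode=mode)

    def backbone(
        self,
        a: float,
        alpha_u: float = 0.05,
        correction: str = "bonferroni",
        mode: str = "auto",
    ) -> filtering.Backbone:
        return filtering.extract_backbone(
            self.network, a, alpha_u=alpha_u, correction=correction, mode=mode
        )

    def loglike(self, a: float, likelihood: str = "composite") -> float:
        if likelihood == "composite":
            return calibration.log_likelihood(self.network, a)
        return calibration.truncated_log_likelihood(self.network, a)

    def sweep(self, **kwargs) -> float:
        return calibration.sweep_a(self.network, **kwargs)

    def optimality(self, **kwargs) -> salience.OptimalityScan:
        return salience.optimality_measures(self.network, **kwargs)

    def fit(
        self,
        bracket: tuple = calibration.DEFAULT_BRACKET,
        likelihood: str = "truncated",
    ) -> "PolyaFilterResults":
        """Maximum-likelihood fit of the reinforcement parameter a."""
        profile = calibration.fit_a_ml(self.network, bracket=bracket, likelihood=likelihood)
        return PolyaFilterResults(model=self, profile=profile)


@dataclass
class PolyaFilterResults:
    """Results of fitting the Pólya null to a network."""

    model: PolyaFilter
    profile: calibration.LikelihoodProfile

    @property
    def a_ml(self) -> float:
        return self.profile.a_ml

    @property
    def llf(self) -> float:
        return self.profile.log_likelihood_ml

    def backbone(
        self,
        alpha_u: float = 0.05,
        correction: str = "bonferroni",
        mode: str = "auto",
    ) -> filtering.Backbone:
        """Backbone at the fitted a (the 'nullest' member of the family)."""
        return self.model.backbone(
            self.a_ml, alpha_u=alpha_u, correction=correction, mode=mode
        )

    def summary(self) -> str:
        net = self.model.network
        p = self.profile
        lines = [
            "                 Pólya Filter Results",
            "=" * 58,
            f"Nodes:            {net.n_nodes:<12d} Links:        {net.n_links}",
            f"Directed:         {str(net.directed):<12} Weights:      {net.weight_kind}",
            f"Likelihood:       {p.likelihood:<12} No. tests:    {p.n_tests}",
            f"a_ML:             {p.a_ml:<12.4g} Log-lik.:     {p.log_likelihood_ml:.4f}",
            f"Bracket:          ({p.bracket[0]:g}, {p.bracket[1]:g})",
            f"At bracket edge:  {p.at_bracket_edge}",
        ]
        if p.pseudo:
            lines.append("Note: real-valued weights; Beta-rate pseudo-likelihood used.")
        lines.append("=" * 58)
        return "\n".join(lines)
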