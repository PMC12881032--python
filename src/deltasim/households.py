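"""Monthly household microsimulation: incomes, coping and poverty.

36 archetype households earn from up to six sources (farming, farm
labour, fishing, forest goods, manufacturing, small business).  Each
month a household matches income and fixed livelihood costs against its
food and non-food needs.  Shortfalls trigger a lexicographic search over
discrete coping actions: first minimise the number of members sent into
temporary agricultural labour, then the number of distinct coping
strategies, then maximise the achieved financial capacity (achieved
expenditure as a fraction of needs) subject to a minimum net savings.
Safety nets (postponed loan repayment, support from friends and family)
apply only when every coping combination falls short.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

OCCUPATIONS = ("farming", "farm_labour", "fishing", "forest", "manufacturing", "business")

LIVELIHOOD_GROUPS = ("farm_based", "mixed", "service")
LANDHOLDING_CLASSES = ("landless", "small", "large")


@dataclass(frozen=True)
class HouseholdArchetype:
    """A representative household type.

    ``base_income_by_source`` is the baseline monthly income vector (one
    entry per occupation, in currency units); ``land_share`` and
    ``labour_share`` convert regional farm output value and farm labour
    demand into this household's farming and farm-labour income;
    ``seasonal_amplitude`` modulates how strongly farm income is
    concentrated in harvest months.  ``weight`` is the archetype's share
    of all households.
    """

    archetype_id: str
    occupation_shares: tuple[float, ...]
    members: int
    land_ha: float
    assets_value: float
    initial_savings: float
    monthly_food_need: float
    monthly_nonfood_need: float
    fixed_livelihood_costs: float
    group: str
    landholding_class: str
    base_income_by_source: tuple[float, ...]
    land_share: float
    labour_share: float
    labour_supply_pm: float  # person-months of farm labour available
    seasonal_amplitude: float = 0.3
    weight: float = 1.0 / 36.0

    def __post_init__(self) -> None:
        if abs(sum(self.occupation_shares) - 1.0) > 1e-6:
            raise ValueError("occupation shares must sum to 1")
        if self.members < 1:
            raise ValueError("at least one member")
        if self.monthly_food_need <= 0 or self.monthly_nonfood_need <= 0:
            raise ValueError("needs must be positive")
        if self.group not in LIVELIHOOD_GROUPS:
            raise ValueError(f"group must be one of {LIVELIHOOD_GROUPS}")
        if self.landholding_class not in LANDHOLDING_CLASSES:
            raise ValueError(f"landholding class must be one of {LANDHOLDING_CLASSES}")


@dataclass
class HouseholdState:
    savings: float
    debt: float
    assets_value: float
    months_in_arrears: int = 0
    achieved_expenditure: float = 0.0
    members_labouring: int = 0
    poor_this_month: bool = False
    hungry_this_month: bool = False
    in_deficit: bool = False

    def __post_init__(self) -> None:
        if self.savings < 0 or self.assets_value < 0 or self.debt < 0:
            raise ValueError("savings, assets and debt must be >= 0")


#: Coping actions in canonical order (monetary actions only; extra
#: labouring is handled by its own lexicographic level).
COPING_ACTIONS = ("use_savings", "sell_assets", "take_loan", "reduce_expenditure")

SAFETY_NETS = ("postpone_repayment", "friends_family_support")


@dataclass(frozen=True)
class CopingPlan:
    """Chosen coping actions with amounts, plus any safety nets used."""

    amounts: dict = field(default_factory=dict)  # action -> currency
    extra_labourers: int = 0
    safety_nets: tuple[str, ...] = ()

    @property
    def actions(self) -> tuple[str, ...]:
        return tuple(a for a, v in self.amounts.items() if v > 0)

    @property
    def n_strategies(self) -> int:
        return len(self.actions) + (1 if self.extra_labourers > 0 else 0)


@dataclass(frozen=True)
class CopingParams:
    n_levels: int = 5  # discrete amounts per action (excluding zero)
    min_savings: float = 0.0
    asset_sale_cap_frac: float = 0.2  # of liquid asset value per month
    loan_cap_months: float = 3.0  # of total monthly needs
    max_expenditure_cut_frac: float = 0.5  # of total needs
    wage_rate: float = 3000.0  # per labourer-month
    monthly_interest: float = 0.01
    repayment_frac: float = 0.1  # of outstanding debt per month
    support_cap_frac: float = 0.5  # friends/family, of total needs
    arrears_seizure_months: int = 12


def monthly_income(
    arch: HouseholdArchetype,
    farm_output_value: float,
    labour_demand: float,
    fish_index: float,
    forest_input: float,
    econ_index: float,
    income_scale: float = 1.0,
    wage_rate: float = 3000.0,
    month_weight_farm: float = 1.0,
) -> dict:
    """Income by source for one month.

    Farming income is the household's land share of the regional farm
    output value; farm labour pays the wage rate on the smaller of the
    household's labour supply and its share of regional demand; fishing
    and forest collection scale with their indices; manufacturing and
    business scale with the economy index.  ``month_weight_farm``
    concentrates farm income into harvest months.
    """
    if min(farm_output_value, labour_demand, fish_index, forest_input, econ_index) < 0:
        raise ValueError("indices and values must be >= 0")
    farming = arch.land_share * farm_output_value * month_weight_farm
    labour = wage_rate * min(arch.labour_supply_pm, arch.labour_share * labour_demand)
    base = arch.base_income_by_source
    income = {
        "farming": farming,
        "farm_labour": labour,
        "fishing": base[2] * fish_index,
        "forest": base[3] * forest_input,
        "manufacturing": base[4] * econ_index,
        "business": base[5] * econ_index,
    }
    return {k: v * income_scale for k, v in income.items()}


def _levels(cap: float, n: int) -> np.ndarray:
    """Strictly positive discretised amounts up to a cap."""
    if cap <= 0:
        return np.array([])
    return np.linspace(cap / n, cap, n)


def optimise_coping(
    state: HouseholdState,
    income: float,
    needs: float,
    poverty_line: float,
    *,
    food_need: Optional[float] = None,
    fixed_costs: float = 0.0,
    params: Optional[CopingParams] = None,
    max_extra_labourers: Optional[int] = None,
) -> tuple[CopingPlan, HouseholdState]:
    """Choose the lexicographically optimal coping plan for one month.

    Objective order: (1) fewest members entering temporary labour, (2)
    fewest distinct coping strategies, (3) highest financial capacity
    (achieved expenditure / needs), subject to end-of-month savings not
    falling below the configured minimum.  Ties break on smaller total
    coping amounts, then canonical action order.  Returns the plan and
    the updated household state; an infeasible month (even with safety
    nets) floors expenditure at what resources allow and sets
    ``in_deficit``.
    """
    if params is None:
        params = CopingParams()
    if food_need is None:
        food_need = 0.6 * needs
    if max_extra_labourers is None:
        max_extra_labourers = 2

    repayment_due = state.debt * (params.repayment_frac + params.monthly_interest)

    def settle(plan: CopingPlan, expenditure: float, repayment: float, transfers: float) -> HouseholdState:
        amounts = plan.amounts
        sale = amounts.get("sell_assets", 0.0)
        loan = amounts.get("take_loan", 0.0)
        labour_income = plan.extra_labourers * params.wage_rate
        new_savings = (
            state.savings
            + income
            + loan
            + sale
            + transfers
            + labour_income
            - expenditure
            - fixed_costs
            - repayment
        )
        new_debt = state.debt
        if repayment > 0:
            principal = max(0.0, repayment - state.debt * params.monthly_interest)
            new_debt = max(0.0, state.debt - principal)
        else:
            new_debt = state.debt * (1.0 + params.monthly_interest)
        new_debt += loan
        arrears = state.months_in_arrears + 1 if "postpone_repayment" in plan.safety_nets else 0
        assets = state.assets_value - sale
        if arrears > params.arrears_seizure_months and new_debt > 0:
            seized = min(assets, new_debt)
            assets -= seized
            new_debt -= seized
        return HouseholdState(
            savings=max(new_savings, 0.0),
            debt=new_debt,
            assets_value=max(assets, 0.0),
            months_in_arrears=arrears,
            achieved_expenditure=expenditure,
            members_labouring=plan.extra_labourers,
            poor_this_month=expenditure < poverty_line,
            hungry_this_month=min(expenditure, food_need) < food_need,
            in_deficit="deficit" in plan.safety_nets,
        )

    caps = {
        "use_savings": max(0.0, state.savings - params.min_savings),
        "sell_assets": state.assets_value * params.asset_sale_cap_frac,
        "take_loan": max(0.0, params.loan_cap_months * needs - state.debt),
        "reduce_expenditure": params.max_expenditure_cut_frac * needs,
    }

    def search(repayment: float, transfer_cap: float, nets: tuple[str, ...]):
        outgo = needs + fixed_costs + repayment
        for n_lab in range(max_extra_labourers + 1):
            resources0 = income + n_lab * params.wage_rate + transfer_cap
            for k in range(len(COPING_ACTIONS) + 1):
                best = None
                for subset in itertools.combinations(COPING_ACTIONS, k):
                    level_sets = [_levels(caps[a], params.n_levels) for a in subset]
                    if any(ls.size == 0 for ls in level_sets):
                        continue
                    for combo in itertools.product(*level_sets):
                        amounts = dict(zip(subset, combo))
                        cut = amounts.get("reduce_expenditure", 0.0)
                        expenditure = needs - cut
                        gain = sum(
                            v for a, v in amounts.items() if a != "reduce_expenditure"
                        )
                        if income + n_lab * params.wage_rate + gain + transfer_cap >= (
                            expenditure + fixed_costs + repayment - 1e-9
                        ):
                            capacity = expenditure / needs
                            total_amt = sum(amounts.values())
                            order = tuple(COPING_ACTIONS.index(a) for a in subset)
                            key = (-capacity, total_amt, order)
                            if best is None or key < best[0]:
                                best = (key, amounts)
                if k == 0:
                    if resources0 >= outgo - 1e-9:
                        return CopingPlan({}, n_lab, nets)
                elif best is not None:
                    return CopingPlan(best[1], n_lab, nets)
        return None

    # Fast path: no shortfall and no action needed.
    if income >= needs + fixed_costs + repayment_due - 1e-9:
        plan = CopingPlan()
        return plan, settle(plan, needs, repayment_due, 0.0)

    plan = search(repayment_due, 0.0, ())
    if plan is not None:
        transfers = 0.0
    else:
        # Safety nets: postpone the loan repayment, then add support.
        plan = search(0.0, 0.0, ("postpone_repayment",))
        if plan is not None:
            transfers = 0.0
            repayment_due = 0.0
        else:
            support = params.support_cap_frac * needs
            plan = search(0.0, support, ("postpone_repayment", "friends_family_support"))
            repayment_due = 0.0
            if plan is not None:
                transfers = support
            else:
                # Deficit: everything maxed, expenditure floored at what
                # remains after fixed costs.
                amounts = {a: caps[a] for a in ("use_savings", "sell_assets", "take_loan") if caps[a] > 0}
                resources = (
                    income
                    + max_extra_labourers * params.wage_rate
                    + sum(amounts.values())
                    + support
                )
                expenditure = max(0.0, resources - fixed_costs)
                plan = CopingPlan(
                    amounts,
                    max_extra_labourers,
                    ("postpone_repayment", "friends_family_support", "deficit"),
                )
                return plan, settle(plan, expenditure, 0.0, support)

    cut = plan.amounts.get("reduce_expenditure", 0.0)
    return plan, settle(plan, needs - cut, repayment_due, transfers)


def classify_poverty(
    state: HouseholdState,
    upper_poverty_line: float,
    food_need: Optional[float] = None,
) -> tuple[bool, bool]:
    """(poor, hungry) flags for a settled month.

    Poor means achieved expenditure strictly below the upper poverty
    line; hungry means the achievable food expenditure (food is
    prioritised within total expenditure) falls short of the food need.
    """
    if upper_poverty_line <= 0:
        raise ValueError("poverty line must be positive")
    poor = state.achieved_expenditure < upper_poverty_line
    if food_need is None:
        hungry = state.hungry_this_month
    else:
        hungry = min(state.achieved_expenditure, food_need) < food_need
    return poor, hungry


def apply_cyclone_shock(
    state: HouseholdState,
    severity: float,
    asset_exposure_frac: float,
) -> HouseholdState:
    """Destroy a fraction of exposed assets after a cyclone.

    ``severity`` in [0, 1] scales the loss of the exposed asset share.
    The poorest households, holding most of their small wealth in exposed
    physical assets with little savings buffer, lose the larger fraction
    of total wealth.
    """
    severity = float(np.clip(severity, 0.0, 1.0))
    loss = state.assets_value * asset_exposure_frac * severity
    return replace(state, assets_value=max(0.0, state.assets_value - loss))
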