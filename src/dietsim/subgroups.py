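"""Canonical 3-digit sub-major food-group codes used across the package.

National survey composition databases organise foods into 3-digit sub-major
groups.  The real taxonomy ships with the (restricted) survey database, so
group membership is input metadata here; these constants define the taxonomy
the synthetic population uses and the default pool selectors the substitution
scenario falls back to.
"""

BREAD = "111"
COOKED_GRAINS = "121"
MILK = "191"
FRUIT_FRESH = "241"
VEGETABLES_FRESH = "251"
MEAT = "281"
FRUIT_VEG_JUICE = "301"
WATER = "311"
TEA_COFFEE = "312"
CAKES_BISCUITS = "411"
PASTRIES_PIES = "421"
CONFECTIONERY = "431"
SAVOURY_SNACKS = "441"
SOFT_DRINKS = "511"
BEER = "521"
WINE = "522"
SPORTS_DRINKS = "531"

#: Fresh/frozen/canned fruit & vegetables — the restrictive substitution pool
#: (dried fruit, potatoes and legumes would carry their own codes and are
#: deliberately not listed).
FRUIT_VEG_SUBGROUPS = frozenset({FRUIT_FRESH, VEGETABLES_FRESH})

#: Water and fruit/vegetable juices — the only admissible replacements for
#: discretionary beverages (tea/coffee is water-based but not a replacement).
BEVERAGE_POOL_SUBGROUPS = frozenset({FRUIT_VEG_JUICE, WATER})
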