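"""Static UN M49 geoscheme table used for the western/non-western split.

The classification rule is purely geographic: a population counts as
"western" when its country falls under UN region 150 (Europe), 021
(Northern America) or 053 (Australia and New Zealand).  Japan (392) is
the one explicit exception: although the UN files it under "developed
regions", it is coded non-western here.  Current geocodes are used
throughout; historical boundary changes are ignored.

The table maps M49 numeric country codes to ``(name, bucket)`` where
``bucket`` is the top-level region code relevant to the split: one of
150, 21, 53 for western regions, or 2 (Africa), 19 (Americas outside
Northern America), 142 (Asia) and 9 (Oceania outside ANZ) otherwise.
It covers the three western regions exhaustively and the non-western
countries that plausibly appear in spousal-height datasets; it is not
the full M49 standard.
"""

from __future__ import annotations

EUROPE = 150
NORTHERN_AMERICA = 21
AUSTRALIA_NZ = 53
AFRICA = 2
AMERICAS_OTHER = 19
ASIA = 142
OCEANIA_OTHER = 9

WESTERN_REGIONS = frozenset({EUROPE, NORTHERN_AMERICA, AUSTRALIA_NZ})

#: M49 country code -> (country name, top-level bucket region code)
M49_COUNTRIES: dict[int, tuple[str, int]] = {
    # --- Europe (150): Northern, Western, Eastern, Southern Europe ---
    248: ("Åland Islands", EUROPE),
    208: ("Denmark", EUROPE),
    233: ("Estonia", EUROPE),
    234: ("Faroe Islands", EUROPE),
    246: ("Finland", EUROPE),
    831: ("Guernsey", EUROPE),
    352: ("Iceland", EUROPE),
    372: ("Ireland", EUROPE),
    833: ("Isle of Man", EUROPE),
    832: ("Jersey", EUROPE),
    428: ("Latvia", EUROPE),
    440: ("Lithuania", EUROPE),
    578: ("Norway", EUROPE),
    744: ("Svalbard and Jan Mayen", EUROPE),
    752: ("Sweden", EUROPE),
    826: ("United Kingdom", EUROPE),
    40: ("Austria", EUROPE),
    56: ("Belgium", EUROPE),
    250: ("France", EUROPE),
    276: ("Germany", EUROPE),
    438: ("Liechtenstein", EUROPE),
    442: ("Luxembourg", EUROPE),
    492: ("Monaco", EUROPE),
    528: ("Netherlands", EUROPE),
    756: ("Switzerland", EUROPE),
    112: ("Belarus", EUROPE),
    100: ("Bulgaria", EUROPE),
    203: ("Czechia", EUROPE),
    348: ("Hungary", EUROPE),
    616: ("Poland", EUROPE),
    498: ("Moldova", EUROPE),
    642: ("Romania", EUROPE),
    643: ("Russian Federation", EUROPE),
    703: ("Slovakia", EUROPE),
    804: ("Ukraine", EUROPE),
    8: ("Albania", EUROPE),
    20: ("Andorra", EUROPE),
    70: ("Bosnia and Herzegovina", EUROPE),
    191: ("Croatia", EUROPE),
    292: ("Gibraltar", EUROPE),
    300: ("Greece", EUROPE),
    336: ("Holy See", EUROPE),
    380: ("Italy", EUROPE),
    470: ("Malta", EUROPE),
    499: ("Montenegro", EUROPE),
    807: ("North Macedonia", EUROPE),
    620: ("Portugal", EUROPE),
    674: ("San Marino", EUROPE),
    688: ("Serbia", EUROPE),
    705: ("Slovenia", EUROPE),
    724: ("Spain", EUROPE),
    # --- Northern America (021) ---
    60: ("Bermuda", NORTHERN_AMERICA),
    124: ("Canada", NORTHERN_AMERICA),
    304: ("Greenland", NORTHERN_AMERICA),
    666: ("Saint Pierre and Miquelon", NORTHERN_AMERICA),
    840: ("United States of America", NORTHERN_AMERICA),
    # --- Australia and New Zealand (053) ---
    36: ("Australia", AUSTRALIA_NZ),
    162: ("Christmas Island", AUSTRALIA_NZ),
    166: ("Cocos (Keeling) Islands", AUSTRALIA_NZ),
    334: ("Heard Island and McDonald Islands", AUSTRALIA_NZ),
    554: ("New Zealand", AUSTRALIA_NZ),
    574: ("Norfolk Island", AUSTRALIA_NZ),
    # --- Asia (142) ---
    392: ("Japan", ASIA),
    156: ("China", ASIA),
    344: ("China, Hong Kong SAR", ASIA),
    446: ("China, Macao SAR", ASIA),
    158: ("Taiwan", ASIA),
    356: ("India", ASIA),
    586: ("Pakistan", ASIA),
    50: ("Bangladesh", ASIA),
    144: ("Sri Lanka", ASIA),
    524: ("Nepal", ASIA),
    64: ("Bhutan", ASIA),
    4: ("Afghanistan", ASIA),
    364: ("Iran", ASIA),
    368: ("Iraq", ASIA),
    376: ("Israel", ASIA),
    400: ("Jordan", ASIA),
    414: ("Kuwait", ASIA),
    422: ("Lebanon", ASIA),
    512: ("Oman", ASIA),
    634: ("Qatar", ASIA),
    682: ("Saudi Arabia", ASIA),
    760: ("Syrian Arab Republic", ASIA),
    784: ("United Arab Emirates", ASIA),
    887: ("Yemen", ASIA),
    48: ("Bahrain", ASIA),
    196: ("Cyprus", ASIA),
    792: ("Türkiye", ASIA),
    795: ("Turkmenistan", ASIA),
    398: ("Kazakhstan", ASIA),
    417: ("Kyrgyzstan", ASIA),
    762: ("Tajikistan", ASIA),
    860: ("Uzbekistan", ASIA),
    51: ("Armenia", ASIA),
    31: ("Azerbaijan", ASIA),
    268: ("Georgia", ASIA),
    410: ("Republic of Korea", ASIA),
    408: ("Democratic People's Republic of Korea", ASIA),
    496: ("Mongolia", ASIA),
    104: ("Myanmar", ASIA),
    116: ("Cambodia", ASIA),
    418: ("Lao People's Democratic Republic", ASIA),
    360: ("Indonesia", ASIA),
    458: ("Malaysia", ASIA),
    608: ("Philippines", ASIA),
    702: ("Singapore", ASIA),
    764: ("Thailand", ASIA),
    704: ("Viet Nam", ASIA),
    626: ("Timor-Leste", ASIA),
    96: ("Brunei Darussalam", ASIA),
    462: ("Maldives", ASIA),
    # --- Africa (002) ---
    12: ("Algeria", AFRICA),
    818: ("Egypt", AFRICA),
    434: ("Libya", AFRICA),
    504: ("Morocco", AFRICA),
    788: ("Tunisia", AFRICA),
    729: ("Sudan", AFRICA),
    231: ("Ethiopia", AFRICA),
    404: ("Kenya", AFRICA),
    834: ("United Republic of Tanzania", AFRICA),
    800: ("Uganda", AFRICA),
    646: ("Rwanda", AFRICA),
    108: ("Burundi", AFRICA),
    706: ("Somalia", AFRICA),
    450: ("Madagascar", AFRICA),
    480: ("Mauritius", AFRICA),
    894: ("Zambia", AFRICA),
    716: ("Zimbabwe", AFRICA),
    508: ("Mozambique", AFRICA),
    454: ("Malawi", AFRICA),
    24: ("Angola", AFRICA),
    516: ("Namibia", AFRICA),
    72: ("Botswana", AFRICA),
    710: ("South Africa", AFRICA),
    426: ("Lesotho", AFRICA),
    748: ("Eswatini", AFRICA),
    566: ("Nigeria", AFRICA),
    288: ("Ghana", AFRICA),
    270: ("Gambia", AFRICA),
    686: ("Senegal", AFRICA),
    466: ("Mali", AFRICA),
    854: ("Burkina Faso", AFRICA),
    562: ("Niger", AFRICA),
    324: ("Guinea", AFRICA),
    384: ("Côte d'Ivoire", AFRICA),
    430: ("Liberia", AFRICA),
    694: ("Sierra Leone", AFRICA),
    768: ("Togo", AFRICA),
    204: ("Benin", AFRICA),
    120: ("Cameroon", AFRICA),
    140: ("Central African Republic", AFRICA),
    148: ("Chad", AFRICA),
    178: ("Congo", AFRICA),
    180: ("Democratic Republic of the Congo", AFRICA),
    266: ("Gabon", AFRICA),
    226: ("Equatorial Guinea", AFRICA),
    # --- Americas outside Northern America (Latin America & Caribbean) ---
    484: ("Mexico", AMERICAS_OTHER),
    320: ("Guatemala", AMERICAS_OTHER),
    340: ("Honduras", AMERICAS_OTHER),
    222: ("El Salvador", AMERICAS_OTHER),
    558: ("Nicaragua", AMERICAS_OTHER),
    188: ("Costa Rica", AMERICAS_OTHER),
    591: ("Panama", AMERICAS_OTHER),
    84: ("Belize", AMERICAS_OTHER),
    192: ("Cuba", AMERICAS_OTHER),
    388: ("Jamaica", AMERICAS_OTHER),
    332: ("Haiti", AMERICAS_OTHER),
    214: ("Dominican Republic", AMERICAS_OTHER),
    780: ("Trinidad and Tobago", AMERICAS_OTHER),
    52: ("Barbados", AMERICAS_OTHER),
    630: ("Puerto Rico", AMERICAS_OTHER),
    76: ("Brazil", AMERICAS_OTHER),
    32: ("Argentina", AMERICAS_OTHER),
    152: ("Chile", AMERICAS_OTHER),
    170: ("Colombia", AMERICAS_OTHER),
    218: ("Ecuador", AMERICAS_OTHER),
    604: ("Peru", AMERICAS_OTHER),
    68: ("Bolivia", AMERICAS_OTHER),
    600: ("Paraguay", AMERICAS_OTHER),
    858: ("Uruguay", AMERICAS_OTHER),
    862: ("Venezuela", AMERICAS_OTHER),
    328: ("Guyana", AMERICAS_OTHER),
    740: ("Suriname", AMERICAS_OTHER),
    254: ("French Guiana", AMERICAS_OTHER),
    # --- Oceania outside Australia/New Zealand ---
    598: ("Papua New Guinea", OCEANIA_OTHER),
    90: ("Solomon Islands", OCEANIA_OTHER),
    242: ("Fiji", OCEANIA_OTHER),
    548: ("Vanuatu", OCEANIA_OTHER),
    540: ("New Caledonia", OCEANIA_OTHER),
    882: ("Samoa", OCEANIA_OTHER),
    776: ("Tonga", OCEANIA_OTHER),
    296: ("Kiribati", OCEANIA_OTHER),
    584: ("Marshall Islands", OCEANIA_OTHER),
    583: ("Micronesia (Federated States of)", OCEANIA_OTHER),
    520: ("Nauru", OCEANIA_OTHER),
    585: ("Palau", OCEANIA_OTHER),
    798: ("Tuvalu", OCEANIA_OTHER),
    258: ("French Polynesia", OCEANIA_OTHER),
    316: ("Guam", OCEANIA_OTHER),
}

#: The three western top-level region codes plus the non-western
#: continental buckets, accepted directly as region codes.
M49_REGIONS: dict[int, str] = {
    EUROPE: "Europe",
    NORTHERN_AMERICA: "Northern America",
    AUSTRALIA_NZ: "Australia and New Zealand",
    AFRICA: "Africa",
    AMERICAS_OTHER: "Americas",
    ASIA: "Asia",
    OCEANIA_OTHER: "Oceania",
    419: "Latin America and the Caribbean",
}


def resolve_bucket(code: int) -> int:
    """Return the top-level bucket region code for an M49 code.

    Accepts either a country code from the packaged table or one of the
    region codes themselves.  Raises ``KeyError`` for codes the table
    cannot resolve.
    """
    code = int(code)
    if code in M49_REGIONS:
        return 19 if code == 419 else code
    if code in M49_COUNTRIES:
        return M49_COUNTRIES[code][1]
    raise KeyError(f"unresolvable M49 code: {code}")


def western_country_codes() -> list[int]:
    """All packaged country codes falling under regions 150/021/053."""
    return sorted(c for c, (_, b) in M49_COUNTRIES.items() if b in WESTERN_REGIONS)


def nonwestern_country_codes() -> list[int]:
    return sorted(c for c, (_, b) in M49_COUNTRIES.items() if b not in WESTERN_REGIONS)
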