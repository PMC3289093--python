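"""Published expression-table rows used as worked-example fixtures.

Each row is (identifier, white RPKM, green RPKM, printed green/white
ratio as a string); the printed string's decimal places define the
precision at which the ratio must be reproduced.
"""

# qRT-PCR verification table (identifier, white, green, printed ratio)
TABLE1 = [
    ("Toc159", 0.0, 23.1, "23.1"),
    ("ACP", 0.0, 18.7, "18.7"),
    ("FtsH8", 0.0, 12.8, "12.8"),
    ("LHCB1.5", 50.6, 320.0, "6.32"),
    ("G4", 7.8, 45.5, "5.83"),
    ("FAR1", 2.0, 8.2, "4.1"),
    ("CRY2", 4.4, 18.6, "4.23"),
    ("HY5", 0.0, 7.1, "7.1"),
    ("PHOT2", 2.0, 6.5, "3.25"),
    ("LHCB5", 24.4, 90.1, "3.69"),
    ("GUN5", 3.6, 14.5, "4.03"),
    ("CIP1", 14.7, 4.1, "0.28"),
    ("LSH7", 9.1, 1.8, "0.2"),
    ("HSP70-1", 59.2, 0.5, "0.01"),
]

# carotenoid biosynthesis / chlorophyll binding / photosystem table
TABLE2 = [
    ("PP038070", 0.3, 7.0, "23.3333"),
    ("PP043130", 0.3, 4.2, "14"),
    ("PP013262", 0.7, 3.5, "5"),
    ("PP011276", 1.1, 4.3, "3.90909"),
    ("PP088927", 5.4, 18.9, "3.5"),
    ("PP019996", 0.2, 36.9, "184.5"),
    ("PP013404", 1.1, 100.8, "91.6364"),
    ("PP042072", 0.2, 12.1, "60.5"),
    ("PP032956", 2.5, 140.7, "56.28"),
    ("PP036244", 0.5, 15.5, "31"),
    ("PP026927", 1.0, 26.9, "26.9"),
    ("PP032648", 0.5, 12.0, "24"),
    ("PP034454", 1.2, 25.7, "21.4167"),
    ("PP014055", 4.5, 90.2, "20.0444"),
    ("PP022096", 1.8, 34.9, "19.3889"),
    ("PP016518", 5.2, 80.2, "15.4231"),
    ("PP036291", 5.6, 85.6, "15.2857"),
    ("PP002791", 0.7, 10.4, "14.8571"),
    ("PP060891", 0.0, 13.8, "13.8"),
    ("PP032891", 0.7, 9.4, "13.4286"),
    ("PP033574", 1.4, 18.1, "12.9286"),
    ("PP043522", 2.1, 25.6, "12.1905"),
    ("PP004292", 6.9, 83.9, "12.1594"),
    ("PP041756", 1.1, 13.3, "12.0909"),
    ("PP004529", 21.5, 259.4, "12.0651"),
    ("PP003367", 14.8, 176.1, "11.8986"),
    ("PP019899", 28.5, 328.4, "11.5228"),
    ("PP020291", 40.5, 445.8, "11.0074"),
    ("PP055138", 0.7, 7.6, "10.8571"),
    ("PP005460", 2.1, 21.5, "10.2381"),
    ("PP020373", 0.0, 9.9, "9.9"),
    ("PP021872", 12.4, 115.0, "9.27419"),
    ("PP034445", 0.9, 8.3, "9.22222"),
    ("PP003971", 13.1, 117.1, "8.93893"),
    ("PP034046", 1.1, 9.2, "8.36364"),
    ("PP033656", 4.0, 31.3, "7.825"),
    ("PP029126", 6.0, 46.1, "7.68333"),
    ("PP005284", 6.7, 47.7, "7.1194"),
    ("PP021031", 36.8, 258.7, "7.02989"),
    ("PP016372", 2.4, 16.7, "6.95833"),
    ("PP022981", 6.9, 47.0, "6.81159"),
    ("PP021682", 14.1, 91.5, "6.48936"),
    ("PP003968", 50.6, 320.0, "6.32411"),
    ("PP020586", 22.7, 135.7, "5.97797"),
    ("PP005425", 5.4, 26.2, "4.85185"),
    ("PP010147", 48.6, 226.7, "4.66461"),
    ("PP003504", 66.3, 305.1, "4.60181"),
    ("PP004840", 40.6, 181.7, "4.47537"),
    ("PP020865", 14.6, 61.6, "4.21918"),
    ("PP032222", 8.6, 34.2, "3.97674"),
    ("PP021166", 104.1, 391.8, "3.76369"),
    ("PP005062", 24.4, 90.1, "3.69262"),
    ("PP033260", 4.3, 15.8, "3.67442"),
    ("PP032950", 102.9, 376.3, "3.65695"),
    ("PP022979", 10.0, 33.0, "3.3"),
    ("PP001298", 3.7, 12.0, "3.24324"),
    ("PP021716", 24.4, 78.8, "3.22951"),
    ("PP003549", 24.1, 74.3, "3.08299"),
    ("PP008642", 0.2, 25.8, "129"),
    ("PP000591", 0.5, 54.9, "109.8"),
    ("PP006879", 0.1, 4.7, "47"),
    ("PP004388", 1.1, 45.3, "41.1818"),
    ("PP016988", 0.2, 4.9, "24.5"),
    ("PP018045", 7.8, 174.6, "22.3846"),
    ("PP036218", 0.3, 5.0, "16.6667"),
    ("PP032734", 1.1, 17.4, "15.8182"),
    ("PP020420", 14.5, 221.7, "15.2897"),
    ("PP018042", 0.0, 14.7, "14.7"),
    ("PP004848", 3.4, 49.6, "14.5882"),
    ("PP014192", 7.3, 103.1, "14.1233"),
    ("PP021663", 4.9, 63.5, "12.9592"),
    ("PP069357", 0.7, 8.2, "11.7143"),
    ("PP005143", 6.3, 68.6, "10.8889"),
    ("PP016409", 7.1, 60.7, "8.5493"),
    ("PP033894", 5.6, 44.7, "7.98214"),
    ("PP014928", 10.7, 84.0, "7.85047"),
    ("PP017397", 10.6, 76.7, "7.23585"),
    ("PP060944", 0.0, 7.1, "7.1"),
    ("PP017005", 0.0, 6.6, "6.6"),
    ("PP021626", 0.0, 6.5, "6.5"),
    ("PP000042", 7.8, 48.3, "6.19231"),
    ("PP022192", 25.2, 130.2, "5.16667"),
    ("PP032949", 6.7, 33.7, "5.02985"),
    ("PP032493", 5.2, 25.1, "4.82692"),
    ("PP033323", 21.5, 100.9, "4.69302"),
    ("PP033241", 6.0, 27.1, "4.51667"),
    ("PP033302", 7.4, 32.5, "4.39189"),
    ("PP005186", 48.6, 205.7, "4.23251"),
    ("PP016053", 22.9, 96.6, "4.21834"),
    ("PP022547", 5.8, 23.8, "4.10345"),
    ("PP012172", 7.3, 29.7, "4.06849"),
    ("PP000003", 17.0, 68.8, "4.04706"),
    ("PP033216", 12.2, 47.9, "3.92623"),
    ("PP041363", 2.0, 7.7, "3.85"),
    ("PP012010", 26.9, 95.3, "3.54275"),
    ("PP033278", 11.6, 40.2, "3.46552"),
    ("PP033227", 10.1, 33.6, "3.32673"),
    ("PP005055", 24.0, 76.9, "3.20417"),
    ("PP039593", 2.1, 6.5, "3.09524"),
    ("PP013176", 7.0, 21.5, "3.07143"),
]


def printed_decimals(ratio_str: str) -> int:
    return len(ratio_str.split(".")[1]) if "." in ratio_str else 0
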