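scenario,BSD,BBOEL,DA,GWO,UEO,NVSA
CT vs. PD (P001),0.2379,0.2539,0.2482,0.1840,0.2537,0.2705
CT vs. T1 (P001),0.2357,0.2516,0.2330,0.2317,0.2531,0.2714
CT vs. T2 (P001),0.1889,0.1990,0.1875,0.1840,0.1974,0.2027
CT vs. PD (P002),0.2447,0.2627,0.2463,0.2373,0.2561,0.2662
CT vs. T1 (P002),0.2403,0.2298,0.2411,0.2332,0.2511,0.2576
CT vs. T2 (P002),0.1985,0.2093,0.2041,0.1943,0.2083,0.2137
CT vs. T1 (P003),0.2689,0.2833,0.2695,0.2399,0.2814,0.2936
CT vs. T2 (P003),0.2081,0.2050,0.2128,0.2054,0.2249,0.2332
CT vs. PD (P004),0.2703,0.2790,0.2681,0.2574,0.2820,0.2863
CT vs. T1 (P004),0.2491,0.2626,0.2528,0.2389,0.2615,0.2672
CT vs. T2 (P004),0.2065,0.2198,0.2136,0.2115,0.2224,0.2239
CT vs. PD (P005),0.2273,0.2467,0.2387,0.2198,0.2386,0.2639
CT vs. T1 (P005),0.2260,0.2441,0.2241,0.2188,0.2326,0.2566
CT vs. T2 (P005),0.2065,0.2198,0.2001,0.1951,0.2133,0.2239
CT vs. PD (P006),0.2333,0.2554,0.2349,0.2338,0.2507,0.2606
CT vs. T1 (P006),0.2322,0.2513,0.2387,0.2232,0.2441,0.2556
CT vs. T2 (P006),0.2000,0.1950,0.1989,0.1957,0.2075,0.2123
CT vs. PD (P007),0.2602,0.2677,0.2498,0.2449,0.2684,0.2848
CT vs. T1 (P007),0.2355,0.2583,0.2458,0.2390,0.2597,0.2735
CT vs. T2 (P007),0.2095,0.2119,0.2136,0.2120,0.2257,0.2333
CT vs. PD (P101),0.2084,0.2000,0.2033,0.2013,0.2173,0.2222
CT vs. T1 (P101),0.1961,0.1862,0.1990,0.1977,0.2121,0.2166
CT vs. T2 (P101),0.1755,0.1800,0.1704,0.1631,0.1796,0.1857
CT vs. PD (P102),0.2127,0.1953,0.2101,0.2079,0.2177,0.2232
CT vs. T1 (P102),0.2176,0.1580,0.2207,0.2169,0.2266,0.2334
CT vs. T2 (P102),0.1829,0.1435,0.1739,0.1761,0.1850,0.1902
CT vs. PD (P103),0.2282,0.1538,0.2203,0.2370,0.2423,0.2427
CT vs. T1 (P103),0.2167,0.1499,0.2135,0.2246,0.2346,0.2369
CT vs. PD (P104),0.2341,0.2544,0.2208,0.2398,0.2557,0.2591
CT vs. T1 (P104),0.2367,0.2548,0.2335,0.2360,0.2567,0.2610
CT vs. T2 (P104),0.2061,0.2176,0.2018,0.1981,0.2201,0.2233
CT vs. T1 (P105),0.1991,0.2060,0.1968,0.1981,0.2053,0.2082
CT vs. T2 (P105),0.1706,0.1749,0.1680,0.1681,0.1798,0.1818
CT vs. T1 (P106),0.2132,0.1581,0.2166,0.2338,0.2360,0.2368
CT vs. T2 (P106),0.1853,0.1832,0.1883,0.1940,0.2047,0.2062
CT vs. T1 (P107),0.1956,0.1568,0.1974,0.1975,0.1989,0.2001
CT vs. T2 (P107),0.1742,0.1772,0.1753,0.1716,0.1776,0.1800
CT vs. T1 (P108),0.2092,0.1912,0.2064,0.2115,0.2168,0.2193
CT vs. T2 (P108),0.1813,0.1677,0.1787,0.1833,0.1895,0.1925
CT vs. T1 (P109),0.2132,0.1846,0.2103,0.1970,0.2252,0.2303
CT vs. T2 (P109),0.1775,0.1740,0.1753,0.1642,0.1848,0.1960
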