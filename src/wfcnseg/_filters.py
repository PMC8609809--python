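"""Static analysis/synthesis filter tables for the wavelet registry.

Coefficients are the standard published Daubechies, Symlet and
(reverse-)biorthogonal spline low-pass filters, stored to full double
precision.  High-pass filters are derived from these by the
quadrature-mirror relations in :mod:`wfcnseg.wavelet_bank`; nothing is
generated numerically at run time.
"""

# Orthogonal families: analysis low-pass only; synthesis filters follow
# from time reversal.
ORTHOGONAL_DEC_LO = {
    "db1": [
        0.7071067811865476, 0.7071067811865476,
    ],
    "db2": [
        -0.12940952255126037, 0.2241438680420134, 0.8365163037378079, 0.48296291314453416,
    ],
    "db3": [
        0.03522629188570953, -0.08544127388202666, -0.13501102001025458, 0.45987750211849154,
        0.8068915093110925, 0.33267055295008263,
    ],
    "db4": [
        -0.010597401785069032, 0.0328830116668852, 0.030841381835560764, -0.18703481171909309,
        -0.027983769416859854, 0.6308807679298589, 0.7148465705529157, 0.2303778133088965,
    ],
    "db5": [
        0.0033357252854737712, -0.012580751999081999, -0.006241490212798274,
        0.07757149384004572, -0.032244869584638375, -0.24229488706638203, 0.13842814590132074,
        0.7243085284377729, 0.6038292697971896, 0.16010239797419293,
    ],
    "db6": [
        -0.0010773010853084796, 0.004777257510945511, 0.0005538422011614961,
        -0.03158203931748603, 0.027522865530305727, 0.09750160558732304, -0.12976686756726194,
        -0.22626469396543983, 0.31525035170919763, 0.7511339080210954, 0.49462389039845306,
        0.11154074335010947,
    ],
    "db7": [
        0.00035371379997452024, -0.0018016407040474908, 0.0004295779729213665,
        0.01255099855609984, -0.01657454163066688, -0.03802993693501441, 0.08061260915108308,
        0.07130921926683026, -0.22403618499387498, -0.14390600392856498, 0.4697822874051931,
        0.7291320908462351, 0.3965393194819173, 0.07785205408500918,
    ],
    "db8": [
        -0.00011747678412476953, 0.0006754494064505693, -0.00039174037337694705,
        -0.004870352993451574, 0.008746094047405777, 0.013981027917398282, -0.044088253930794755,
        -0.017369301001807547, 0.12874742662047847, 0.0004724845739132828, -0.2840155429615469,
        -0.015829105256349306, 0.5853546836542067, 0.6756307362972898, 0.31287159091429995,
        0.05441584224310401,
    ],
    "db9": [
        3.93473203162716e-05, -0.0002519631889427101, 0.00023038576352319597,
        0.0018476468830562265, -0.00428150368246343, -0.004723204757751397, 0.022361662123679096,
        0.00025094711483145197, -0.06763282906132997, 0.03072568147933338, 0.14854074933810638,
        -0.09684078322297646, -0.2932737832791749, 0.13319738582500756, 0.6572880780513005,
        0.6048231236901112, 0.24383467461259034, 0.038077947363878345,
    ],
    "db10": [
        -1.3264202894521244e-05, 9.358867032006959e-05, -0.00011646685512928545,
        -0.0006858566949597116, 0.001992405295185056, 0.001395351747052901, -0.010733175483330575,
        0.0036065535669561697, 0.033212674059341, -0.029457536821875813, -0.07139414716639708,
        0.09305736460357235, 0.12736934033579325, -0.19594627437737705, -0.24984642432731538,
        0.2811723436605775, 0.6884590394536035, 0.5272011889317256, 0.1881768000776915,
        0.026670057900555554,
    ],
    "sym2": [
        -0.12940952255092145, 0.22414386804185735, 0.836516303737469, 0.48296291314469025,
    ],
    "sym3": [
        0.035226291882100656, -0.08544127388224149, -0.13501102001039084, 0.4598775021193313,
        0.8068915093133388, 0.3326705529509569,
    ],
    "sym4": [
        -0.07576571478927333, -0.02963552764599851, 0.49761866763201545, 0.8037387518059161,
        0.29785779560527736, -0.09921954357684722, -0.012603967262037833, 0.0322231006040427,
    ],
    "sym5": [
        0.027333068345077982, 0.029519490925774643, -0.039134249302383094, 0.1993975339773936,
        0.7234076904024206, 0.6339789634582119, 0.01660210576452232, -0.17532808990845047,
        -0.021101834024758855, 0.019538882735286728,
    ],
    "sym6": [
        0.015404109327027373, 0.0034907120842174702, -0.11799011114819057, -0.048311742585633,
        0.4910559419267466, 0.787641141030194, 0.3379294217276218, -0.07263752278646252,
        -0.021060292512300564, 0.04472490177066578, 0.0017677118642428036, -0.007800708325034148,
    ],
    "sym7": [
        0.002681814568257878, -0.0010473848886829163, -0.01263630340325193, 0.03051551316596357,
        0.0678926935013727, -0.049552834937127255, 0.017441255086855827, 0.5361019170917628,
        0.767764317003164, 0.2886296317515146, -0.14004724044296152, -0.10780823770381774,
        0.004010244871533663, 0.010268176708511255,
    ],
    "sym8": [
        -0.0033824159510061256, -0.0005421323317911481, 0.03169508781149298,
        0.007607487324917605, -0.1432942383508097, -0.061273359067658524, 0.4813596512583722,
        0.7771857517005235, 0.3644418948353314, -0.05194583810770904, -0.027219029917056003,
        0.049137179673607506, 0.003808752013890615, -0.01495225833704823, -0.0003029205147213668,
        0.0018899503327594609,
    ],
}

# Biorthogonal spline families: analysis and synthesis low-pass differ.
# Lists are zero-padded to a common even length per kernel.
BIORTHOGONAL_LO = {
    "bior1.1": (
        [
            0.7071067811865476, 0.7071067811865476,
        ],
        [
            0.7071067811865476, 0.7071067811865476,
        ],
    ),
    "bior1.3": (
        [
            -0.08838834764831845, 0.08838834764831845, 0.7071067811865476, 0.7071067811865476,
            0.08838834764831845, -0.08838834764831845,
        ],
        [
            0.0, 0.0, 0.7071067811865476, 0.7071067811865476, 0.0, 0.0,
        ],
    ),
    "bior2.2": (
        [
            0.0, -0.1767766952966369, 0.3535533905932738, 1.0606601717798212, 0.3535533905932738,
            -0.1767766952966369,
        ],
        [
            0.0, 0.3535533905932738, 0.7071067811865476, 0.3535533905932738, 0.0,
            0.0,
        ],
    ),
    "bior3.1": (
        [
            -0.3535533905932738, 1.0606601717798212, 1.0606601717798212, -0.3535533905932738,
        ],
        [
            0.1767766952966369, 0.5303300858899106, 0.5303300858899106, 0.1767766952966369,
        ],
    ),
    "bior4.4": (
        [
            0.0, 0.03782845550726404, -0.023849465019556843, -0.11062440441843718,
            0.37740285561283066, 0.8526986790088938, 0.37740285561283066, -0.11062440441843718,
            -0.023849465019556843, 0.03782845550726404,
        ],
        [
            0.0, -0.06453888262869706, -0.04068941760916406, 0.41809227322161724,
            0.7884856164055829, 0.41809227322161724, -0.04068941760916406, -0.06453888262869706,
            0.0, 0.0,
        ],
    ),
    "rbio1.1": (
        [
            0.7071067811865476, 0.7071067811865476,
        ],
        [
            0.7071067811865476, 0.7071067811865476,
        ],
    ),
    "rbio2.2": (
        [
            0.0, 0.0, 0.3535533905932738, 0.7071067811865476, 0.3535533905932738,
            0.0,
        ],
        [
            -0.1767766952966369, 0.3535533905932738, 1.0606601717798212, 0.3535533905932738,
            -0.1767766952966369, 0.0,
        ],
    ),
}

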