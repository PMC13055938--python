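"""Static name frequency lists for the synthetic cohort generator.

A packaged list (rather than a live name-generator service) keeps runs
network-free and byte-reproducible under a fixed seed.  Lists are ordered by
approximate US frequency rank; sampling weights follow a mild Zipf profile so
common names recur the way they do in real registries without making
name+birth-date collisions dominant.
"""

from __future__ import annotations

import numpy as np

SURNAMES = [
    "SMITH", "JOHNSON", "WILLIAMS", "BROWN", "JONES", "GARCIA", "MILLER",
    "DAVIS", "RODRIGUEZ", "MARTINEZ", "HERNANDEZ", "LOPEZ", "GONZALEZ",
    "WILSON", "ANDERSON", "THOMAS", "TAYLOR", "MOORE", "JACKSON", "MARTIN",
    "LEE", "PEREZ", "THOMPSON", "WHITE", "HARRIS", "SANCHEZ", "CLARK",
    "RAMIREZ", "LEWIS", "ROBINSON", "WALKER", "YOUNG", "ALLEN", "KING",
    "WRIGHT", "SCOTT", "TORRES", "NGUYEN", "HILL", "FLORES", "GREEN",
    "ADAMS", "NELSON", "BAKER", "HALL", "RIVERA", "CAMPBELL", "MITCHELL",
    "CARTER", "ROBERTS", "GOMEZ", "PHILLIPS", "EVANS", "TURNER", "DIAZ",
    "PARKER", "CRUZ", "EDWARDS", "COLLINS", "REYES", "STEWART", "MORRIS",
    "MORALES", "MURPHY", "COOK", "ROGERS", "GUTIERREZ", "ORTIZ", "MORGAN",
    "COOPER", "PETERSON", "BAILEY", "REED", "KELLY", "HOWARD", "RAMOS",
    "KIM", "COX", "WARD", "RICHARDSON", "WATSON", "BROOKS", "CHAVEZ",
    "WOOD", "JAMES", "BENNETT", "GRAY", "MENDOZA", "RUIZ", "HUGHES",
    "PRICE", "ALVAREZ", "CASTILLO", "SANDERS", "PATEL", "MYERS", "LONG",
    "ROSS", "FOSTER", "JIMENEZ", "POWELL", "JENKINS", "PERRY", "RUSSELL",
    "SULLIVAN", "BELL", "COLEMAN", "BUTLER", "HENDERSON", "BARNES",
    "GONZALES", "FISHER", "VASQUEZ", "SIMMONS", "ROMERO", "JORDAN",
    "PATTERSON", "ALEXANDER", "HAMILTON", "GRAHAM", "REYNOLDS", "GRIFFIN",
    "WALLACE", "MORENO", "WEST", "COLE", "HAYES", "BRYANT", "HERRERA",
    "GIBSON", "ELLIS", "TRAN", "MEDINA", "AGUILAR", "STEVENS", "MURRAY",
    "FORD", "CASTRO", "MARSHALL", "OWENS", "HARRISON", "FERNANDEZ",
    "MCDONALD", "WOODS", "WASHINGTON", "KENNEDY", "WELLS", "VARGAS",
    "HENRY", "CHEN", "FREEMAN", "WEBB", "TUCKER", "GUZMAN", "BURNS",
    "CRAWFORD", "OLSON", "SIMPSON", "PORTER", "HUNTER", "GORDON", "MENDEZ",
    "SILVA", "SHAW", "SNYDER", "MASON", "DIXON", "MUNOZ", "HUNT", "HICKS",
    "HOLMES", "PALMER", "WAGNER", "BLACK", "ROBERTSON", "BOYD", "ROSE",
    "STONE", "SALAZAR", "FOX", "WARREN", "MILLS", "MEYER", "RICE",
    "SCHMIDT", "GARZA", "DANIELS", "FERGUSON", "NICHOLS", "STEPHENS",
    "SOTO", "WEAVER", "RYAN", "GARDNER", "PAYNE", "GRANT", "DUNN",
    "KELLEY", "SPENCER", "HAWKINS", "ARNOLD", "PIERCE", "VAZQUEZ",
]

FEMALE_GIVEN = [
    "MARY", "PATRICIA", "JENNIFER", "LINDA", "ELIZABETH", "BARBARA",
    "SUSAN", "JESSICA", "SARAH", "KAREN", "LISA", "NANCY", "BETTY",
    "MARGARET", "SANDRA", "ASHLEY", "KIMBERLY", "EMILY", "DONNA",
    "MICHELLE", "CAROL", "AMANDA", "DOROTHY", "MELISSA", "DEBORAH",
    "STEPHANIE", "REBECCA", "SHARON", "LAURA", "CYNTHIA", "KATHLEEN",
    "AMY", "ANGELA", "SHIRLEY", "ANNA", "BRENDA", "PAMELA", "EMMA",
    "NICOLE", "HELEN", "SAMANTHA", "KATHERINE", "CHRISTINE", "DEBRA",
    "RACHEL", "CAROLYN", "JANET", "CATHERINE", "MARIA", "HEATHER",
    "DIANE", "RUTH", "JULIE", "OLIVIA", "JOYCE", "VIRGINIA", "VICTORIA",
    "KELLY", "LAUREN", "CHRISTINA", "JOAN", "EVELYN", "JUDITH", "MEGAN",
    "ANDREA", "CHERYL", "HANNAH", "JACQUELINE", "MARTHA", "GLORIA",
    "TERESA", "ANN", "SARA", "MADISON", "FRANCES", "KATHRYN", "JANICE",
    "JEAN", "ABIGAIL", "ALICE", "JULIA", "JUDY", "SOPHIA", "GRACE",
    "DENISE", "AMBER", "DORIS", "MARILYN", "DANIELLE", "BEVERLY",
    "ISABELLA", "THERESA", "DIANA", "NATALIE", "BRITTANY", "CHARLOTTE",
    "MARIE", "KAYLA", "ALEXIS", "LORI",
]

MALE_GIVEN = [
    "JAMES", "ROBERT", "JOHN", "MICHAEL", "DAVID", "WILLIAM", "RICHARD",
    "JOSEPH", "THOMAS", "CHARLES", "CHRISTOPHER", "DANIEL", "MATTHEW",
    "ANTHONY", "MARK", "DONALD", "STEVEN", "PAUL", "ANDREW", "JOSHUA",
    "KENNETH", "KEVIN", "BRIAN", "GEORGE", "TIMOTHY", "RONALD", "EDWARD",
    "JASON", "JEFFREY", "RYAN", "JACOB", "GARY", "NICHOLAS", "ERIC",
    "JONATHAN", "STEPHEN", "LARRY", "JUSTIN", "SCOTT", "BRANDON",
    "BENJAMIN", "SAMUEL", "GREGORY", "ALEXANDER", "FRANK", "PATRICK",
    "RAYMOND", "JACK", "DENNIS", "JERRY", "TYLER", "AARON", "JOSE",
    "ADAM", "NATHAN", "HENRY", "DOUGLAS", "ZACHARY", "PETER", "KYLE",
    "ETHAN", "WALTER", "NOAH", "JEREMY", "CHRISTIAN", "KEITH", "ROGER",
    "TERRY", "AUSTIN", "SEAN", "GERALD", "CARL", "HAROLD", "DYLAN",
    "ARTHUR", "LAWRENCE", "JORDAN", "JESSE", "BRYAN", "BILLY", "BRUCE",
    "GABRIEL", "JOE", "LOGAN", "ALAN", "JUAN", "ALBERT", "WILLIE",
    "ELIJAH", "WAYNE", "RANDY", "VINCENT", "MASON", "ROY", "RALPH",
    "BOBBY", "RUSSELL", "BRADLEY", "PHILIP", "EUGENE",
]


def rank_weights(n: int, s: float = 0.7) -> np.ndarray:
    """Normalized Zipf-like sampling weights for a list of ``n`` ranked names."""
    w = 1.0 / np.arange(1, n + 1) ** s
    return w / w.sum()
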