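# Selection query language

Selections filter an entity (or a previous selection) down to a view.
A query is a Boolean combination of property predicates, optionally with
proximity (`within`) clauses.

## Examples

```
aname=CA                       # all Cα atoms
aname=CA,CB and cname=A        # comma list = disjunction
rnum=10:20                     # inclusive residue-number range
not rname=HOH                  # everything but water
occ>=0.5 and abfac<40          # numeric comparisons
5 <> [rname=HEM]               # atoms within 5 Å of any HEM atom
3.5 <> {1.0, 2.0, 3.0}         # atoms within 3.5 Å of a literal point
gr:conservation>0.5            # residue-level generic property
```

## Built-in properties

| id         | level   | type  | meaning                 |
|------------|---------|-------|-------------------------|
| `aname`    | atom    | str   | atom name               |
| `rname`    | residue | str   | residue (compound) name |
| `rnum`     | residue | int   | residue number          |
| `cname`    | chain   | str   | chain name              |
| `ele`      | atom    | str   | chemical element        |
| `occ`      | atom    | float | occupancy               |
| `abfac`    | atom    | float | isotropic B factor      |
| `ishetatm` | atom    | bool  | HETATM record flag      |
| `charge`   | atom    | float | formal charge           |

Generic properties use level prefixes: `ga:` (atom), `gr:` (residue),
`gc:` (chain), followed by the key, e.g. `ga:score>0.25`.  Atoms lacking
the key simply do not match — no error.  String comparisons are
case-sensitive and support only `=`/`!=`.

Residue- and chain-level predicates match *all atoms* of matching
residues/chains.  `within` promotes exactly the matched atoms (no residue
promotion); its reference sub-query is matched against the underlying
entity, so a chained selection can still measure distances to atoms outside
the current view — this keeps selection idempotent.

## Grammar (EBNF)

```ebnf
query      = or_expr ;
or_expr    = and_expr { "or" and_expr } ;
and_expr   = not_expr { "and" not_expr } ;
not_expr   = "not" not_expr | primary ;
primary    = "(" or_expr ")" | within | predicate ;

within     = number "<>" ( "[" or_expr "]"
                         | "{" number "," number "," number "}" ) ;

predicate  = property op value { "," value } ;
property   = builtin | generic ;
builtin    = "aname" | "rname" | "rnum" | "cname" | "ele"
           | "occ" | "abfac" | "ishetatm" | "charge" ;
generic    = ( "ga" | "gr" | "gc" ) ":" key ;
op         = "=" | "!=" | "<" | "<=" | ">" | ">=" ;
value      = number [ ":" number ]        (* inclusive range *)
           | word | boolean ;
boolean    = "true" | "false" | "1" | "0" ;
```

`not` binds tighter than `and`, which binds tighter than `or`.  The radius
of `within` is in ångströms and must be non-negative; range bounds must
satisfy lower ≤ upper.  Words may contain letters, digits and `' * _ . +`
(so primed atom names like `O3'` parse unquoted).
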